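"""End-to-end orchestration: normalize → collapse → DE → intersections →
enrichment → focal correlation → consensus → network → cascade → activation.

A run is driven by a YAML config naming the input files and thresholds.
Every stage writes plain TSV/JSON outputs keyed by stage name into the
output directory and the run ends with a manifest recording the config
hash, seed and a SHA-256 checksum per output file; re-running the same
config reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cascade_activation as ca
from . import diffexp, integration, mirdiana, network, preprocess
from .io_formats import (
    UsageError,
    read_alias_table,
    read_expression_tsv,
    read_gmt,
    read_target_db,
    write_expression_tsv,
    write_network_json,
)

logger = logging.getLogger(__name__)

CONTRASTS = {"E": ("EC", "ET"), "I": ("IC", "IT"), "K": ("KC", "KT")}
STAGES = (
    "normalize",
    "collapse",
    "diffexp",
    "intersections",
    "enrichment",
    "correlation",
    "consensus",
    "network",
    "cascade",
    "activation",
)


@dataclass
class RunConfig:
    mrna: Path
    mirna: Path
    protein: Path
    design: Path
    targets: dict[str, Path]
    aliases: Path
    gene_sets: Path
    outdir: Path
    probe_map: Path | None = None
    seed: int = 0
    alpha: float = diffexp.DEFAULT_ALPHA
    theta: dict[str, float] = field(default_factory=lambda: dict(diffexp.DEFAULT_THETA))
    focal_gene: str = "Brca1"
    min_consensus: int = 1
    ring_filter: float = 0.3
    cascade_step: float = 2.0
    cascade_condition: str = "T"
    activation_set: str | None = None
    top_k: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with path.open() as fh:
            raw = yaml.safe_load(fh)
        inputs = raw.get("inputs", {})
        thresholds = raw.get("thresholds", {})
        net = raw.get("network", {})
        casc = raw.get("cascade", {})
        base = path.parent

        def p(key):
            if key not in inputs:
                raise UsageError(f"config missing inputs.{key}")
            return (base / inputs[key]).resolve()

        targets = {
            name: (base / t).resolve() for name, t in inputs.get("targets", {}).items()
        }
        if not targets:
            raise UsageError("config missing inputs.targets")
        return cls(
            mrna=p("mrna"),
            mirna=p("mirna"),
            protein=p("protein"),
            design=p("design"),
            targets=targets,
            aliases=p("aliases"),
            gene_sets=p("gene_sets"),
            probe_map=(base / inputs["probe_map"]).resolve() if "probe_map" in inputs else None,
            outdir=(base / raw.get("outdir", "results")).resolve(),
            seed=int(raw.get("seed", 0)),
            alpha=float(thresholds.get("alpha", diffexp.DEFAULT_ALPHA)),
            theta={
                layer: float(thresholds.get(f"theta_{layer}", diffexp.DEFAULT_THETA[layer]))
                for layer in diffexp.DEFAULT_THETA
            },
            focal_gene=net.get("focal_gene", "Brca1"),
            min_consensus=int(net.get("min_consensus", 1)),
            ring_filter=float(net.get("ring_filter", 0.3)),
            cascade_step=float(casc.get("step", 2.0)),
            cascade_condition=casc.get("condition", "T"),
            activation_set=raw.get("activation_set"),
            top_k=int(raw.get("top_k", 50)),
        )

    def validate(self) -> None:
        paths = [self.mrna, self.mirna, self.protein, self.design, self.aliases,
                 self.gene_sets, *self.targets.values()]
        if self.probe_map:
            paths.append(self.probe_map)
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise UsageError(f"input paths do not exist: {missing}")

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items())}, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_frame(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Any stage failure aborts the run with the stage name and cause; outputs
    produced so far are retained and a ``failed`` marker names the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }
    state: dict = {}

    def record(stage: str, outputs: dict[str, Path], **info) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "outputs": {p.name: _sha256(p) for p in outputs.values()},
                "info": info,
            }
        )
        logger.info("stage %s: %s", stage, info)

    stage = "start"
    try:
        for stage in STAGES:
            outputs = _STAGE_FUNCS[stage](config, state, outdir)
            record(stage, outputs, **state.pop("_info", {}))
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        (outdir / "failed").write_text(f"{stage}: {exc}\n")
        raise StageFailure(stage, exc) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


# --- stage implementations -------------------------------------------------


def _stage_normalize(config: RunConfig, state: dict, outdir: Path) -> dict[str, Path]:
    design = preprocess.SampleDesign.read_tsv(config.design)
    state["design"] = design
    outputs = {}
    for layer, path in (("mrna", config.mrna), ("mirna", config.mirna), ("protein", config.protein)):
        table = read_expression_tsv(path, layer)
        design.validate_table(table)
        norm = preprocess.quantile_normalize(table)
        out = outdir / f"normalize_{layer}.tsv"
        write_expression_tsv(norm, out)
        outputs[layer] = out
        state[layer] = norm
    state["_info"] = {
        "rows": {l: len(state[l].molecule_ids) for l in ("mrna", "mirna", "protein")}
    }
    return outputs


def _stage_collapse(config: RunConfig, state: dict, outdir: Path) -> dict[str, Path]:
    table = state["mrna"]
    if config.probe_map:
        pm = pd.read_csv(config.probe_map, sep="\t", dtype=str)
        probe_map = dict(zip(pm.iloc[:, 0], pm.iloc[:, 1]))
    else:  # expression rows already are genes; identity collapse
        probe_map = {m: m for m in table.molecule_ids}
    collapsed = preprocess.collapse_probes(table, probe_map)
    out = outdir / "collapse_mrna.tsv"
    write_expression_tsv(collapsed, out)
    state["mrna_genes"] = collapsed
    state["_info"] = {"probes": len(table.molecule_ids), "genes": len(collapsed.molecule_ids)}
    return {"mrna_genes": out}


def _stage_diffexp(config: RunConfig, state: dict, outdir: Path) -> dict[str, Path]:
    design = state["design"]
    outputs = {}
    de: dict[str, dict[str, diffexp.DEResult]] = {}
    for layer, key in (("mrna", "mrna_genes"), ("mirna", "mirna"), ("protein", "protein")):
        thr = diffexp.DEThresholds(theta=config.theta[layer], alpha=config.alpha)
        de[layer] = {}
        for cell, contrast in CONTRASTS.items():
            result = diffexp.student_t_de(state[key], design, contrast, thr)
            de[layer][cell] = result
            out = outdir / f"diffexp_{layer}_{contrast[1]}_vs_{contrast[0]}.tsv"
            _write_frame(result.table, out)
            outputs[f"{layer}_{cell}"] = out
    state["de"] = de
    state["_info"] = {
        "passing": {
            layer: {cell: int(r.table["passes"].sum()) for cell, r in results.items()}
            for layer, results in de.items()
        }
    }
    return outputs


def _stage_intersections(config: RunConfig, state: dict, outdir: Path) -> dict[str, Path]:
    outputs = {}
    shared_counts = {}
    for layer, results in state["de"].items():
        for direction in ("up", "down"):
            frame = diffexp.shared_de(results, direction)
            out = outdir / f"shared_{layer}_{direction}.tsv"
            _write_frame(frame, out)
            shared_counts[f"{layer}_{direction}"] = len(frame)
            outputs[f"{layer}_{direction}"] = out
    state["shared_counts"] = shared_counts
    state["_info"] = dict(shared_counts)
    return outputs


def _stage_enrichment(config: RunConfig, state: dict, outdir: Path) -> dict[str, Path]:
    collection = read_gmt(config.gene_sets)
    universe = {
        m
        for r in state["de"]["mrna"].values()
        for m in r.table.index[r.table["tested"]]
    }
    results = state["de"]["mrna"]
    outputs = {}
    for direction in ("up", "down"):
        query = set(diffexp.shared_de(results, direction).index) & universe
        enr = diffexp.hypergeom_enrich(query, collection, universe)
        out = outdir / f"enrichment_{direction}.tsv"
        _write_frame(enr.table, out)
        outputs[direction] = out
    state["_info"] = {"universe": len(universe), "sets": len(collection)}
    return outputs


def _stage_correlation(config: RunConfig, state: dict, outdir: Path) -> dict[str, Path]:
    ranking = integration.focal_correlation(state["mrna_genes"], config.focal_gene, config.top_k)
    frame = ranking.correlations.rename("r").to_frame()
    frame["top_positive"] = frame.index.isin(ranking.top_positive)
    frame["top_negative"] = frame.index.isin(ranking.top_negative)
    out = outdir / "correlation_focal.tsv"
    _write_frame(frame.sort_values("r", ascending=False), out)
    pairs = integration.match_gene_protein(
        state["mrna_genes"], state["protein"], state["design"], preprocess.CELL_GROUPS
    )
    fits = {}
    for method in ("ordinary", "robust", "orthogonal"):
        fit = integration.fit_regression(pairs, method)
        fits[method] = {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "pearson_r": fit.pearson_r,
            "n_points": fit.n_points,
        }
    fit_out = outdir / "correlation_protein_gene.json"
    fit_out.write_text(json.dumps(fits, indent=1, sort_keys=True) + "\n")
    state["_info"] = {"focal": config.focal_gene, "ols_slope": fits["ordinary"]["slope"]}
    return {"focal": out, "protein_gene": fit_out}


def _stage_consensus(config: RunConfig, state: dict, outdir: Path) -> dict[str, Path]:
    aliases = read_alias_table(config.aliases)
    dbs = [read_target_db(path, name) for name, path in sorted(config.targets.items())]
    consensus = mirdiana.build_consensus(dbs, aliases)
    out = outdir / "consensus.tsv"
    consensus.write_tsv(out)
    state["consensus"] = consensus
    state["_info"] = {"pairs": len(consensus.memberships), "dbs": len(dbs)}
    return {"consensus": out}


def _stage_network(config: RunConfig, state: dict, outdir: Path) -> dict[str, Path]:
    params = network.NetworkParams(
        focal_gene=config.focal_gene,
        min_consensus=config.min_consensus,
        ring_filter=config.ring_filter,
    )
    net = network.build_ring_network(
        state["mrna_genes"], state["mirna"], state["protein"],
        state["design"], state["consensus"], params,
    )
    out = outdir / "network.json"
    write_network_json(net, out)
    de_t = {layer: state["de"][layer]["E"] for layer in state["de"]}
    summary = network.diff_distribution_summary(de_t, state["consensus"], params)
    sum_out = outdir / "network_summary.tsv"
    _write_frame(summary, sum_out, index=False)
    state["_info"] = {
        "ring1": len(net.ring(1)), "ring2": len(net.ring(2)), "ring3": len(net.ring(3))
    }
    return {"network": out, "summary": sum_out}


def _stage_cascade(config: RunConfig, state: dict, outdir: Path) -> dict[str, Path]:
    params = ca.CascadeParams(step=config.cascade_step, condition=config.cascade_condition)
    result = ca.find_cascades(state["mrna_genes"], state["design"], params)
    counts = result.counts()
    out = outdir / "cascade_counts.tsv"
    _write_frame(counts, out, index=False)
    rows = []
    for (seq, d), mols in result.lists.items():
        for m in mols:
            rows.append({"sequence": "->".join(seq), "direction": d, "transcript": m})
    lists_out = outdir / "cascade_transcripts.tsv"
    _write_frame(pd.DataFrame(rows, columns=["sequence", "direction", "transcript"]), lists_out, index=False)
    flags = ca.cross_condition_check(result, state["mrna_genes"], state["design"])
    flags_out = outdir / "cascade_cross_condition.tsv"
    _write_frame(flags.rename("tme_above_control").to_frame(), flags_out)
    state["_info"] = {
        "->".join(seq) + f":{d}": len(mols) for (seq, d), mols in result.lists.items()
    }
    return {"counts": out, "transcripts": lists_out, "cross_condition": flags_out}


def _stage_activation(config: RunConfig, state: dict, outdir: Path) -> dict[str, Path]:
    collection = read_gmt(config.gene_sets)
    set_name = config.activation_set or next(iter(collection.sets))
    if set_name not in collection.sets:
        raise UsageError(f"activation set {set_name!r} not in the collection")
    profile = ca.categorize_expression(
        state["mrna_genes"], state["design"], collection.sets[set_name], set_name
    )
    out = outdir / "activation_profile.tsv"
    _write_frame(profile.categories, out)
    last = ca.last_activated(profile)
    last_out = outdir / "activation_last.json"
    last_out.write_text(json.dumps({"set": set_name, "last_activated": last}) + "\n")
    state["_info"] = {"set": set_name, "last_activated": last}
    return {"profile": out, "last": last_out}


_STAGE_FUNCS = {
    "normalize": _stage_normalize,
    "collapse": _stage_collapse,
    "diffexp": _stage_diffexp,
    "intersections": _stage_intersections,
    "enrichment": _stage_enrichment,
    "correlation": _stage_correlation,
    "consensus": _stage_consensus,
    "network": _stage_network,
    "cascade": _stage_cascade,
    "activation": _stage_activation,
}
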