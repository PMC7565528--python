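"""Synthetic multi-omics datasets with the statistical structure of the
liver-metastasis TME study design.

Three layers are emitted on the log2 scale with Gaussian noise around
per-molecule baselines: mRNA (4 replicates per cell×condition group), miRNA
(3 replicates, except 2 for EC and KT) and protein (9/7/6/6/5/5 replicates
for EC/ET/IC/IT/KC/KT, with missing-completely-at-random dropout).  Primary
tumor (TP) and liver-metastasis (TM) sample groups are optional extras that
never enter differential contrasts.  Effects are *planted* and recorded as
ground truth: differential shifts per contrast, monotone activation
cascades across the cell types in the TME condition, miRNA→gene
anti-regulation, a protein-vs-transcript linear trend, focal-gene
correlation partners, and an activation gene set with one late-switching
member.  Four miRNA-target database fixtures are written with controlled
per-database membership of each planted pair.  All randomness derives from
a single integer seed; a fixed seed reproduces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    AliasTable,
    ExpressionTable,
    GeneSetCollection,
    TargetDBFile,
    TARGET_DB_DIALECTS,
    UsageError,
    write_alias_table,
    write_expression_tsv,
    write_gmt,
    write_target_db,
)
from .preprocess import CELL_GROUPS, SampleDesign

MRNA_REPLICATES = {g: 4 for g in CELL_GROUPS}
MIRNA_REPLICATES = {"EC": 2, "ET": 3, "IC": 3, "IT": 3, "KC": 3, "KT": 2}
PROTEIN_REPLICATES = {"EC": 9, "ET": 7, "IC": 6, "IT": 6, "KC": 5, "KT": 5}
TUMOR_REPLICATES = 2  # TP/TM extras (descriptive only)


@dataclass(frozen=True)
class PlantedDE:
    """A molecule shifted by ``effect`` log2 units in the test group of a
    (reference, test) contrast."""

    molecule: str
    layer: str
    contrast: tuple[str, str]
    effect: float


@dataclass(frozen=True)
class PlantedCascade:
    """A transcript whose TME group means rise by ``increment`` per step
    along an ordered cell-type triple (e.g. E→I→K)."""

    gene: str
    sequence: tuple[str, str, str]
    increment: float
    condition: str = "T"


@dataclass(frozen=True)
class PlantedTarget:
    """A miRNA→gene interaction asserted by ``dbs`` of the four databases;
    when the miRNA is planted up, the gene is pushed down by
    ``suppression`` × the miRNA effect in the same groups."""

    mirna: str
    gene: str
    dbs: frozenset[str]
    suppression: float = 0.0


@dataclass(frozen=True)
class FocalPartner:
    """A gene constructed to correlate (r of given sign/magnitude) with the
    focal gene across all samples."""

    gene: str
    correlation: float


@dataclass(frozen=True)
class PlantedActivation:
    """An activation gene set: most members high in every group, switch
    members low in all control and high in all TME groups."""

    set_name: str = "ACTIVATION_COMPLEX"
    always_high: tuple[str, ...] = ()
    switch: tuple[str, ...] = ()
    low_level: float = 2.0
    high_level: float = 14.0


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study design."""

    n_genes: int = 400
    n_mirnas: int = 150
    n_proteins: int = 120
    baseline_mean: float = 8.0
    baseline_between_sd: float = 2.0  # spread of per-molecule baselines
    noise_sd: float = 0.3  # within-group replicate noise (log2)
    include_tumor_groups: bool = True
    planted_de: list[PlantedDE] = field(default_factory=list)
    planted_cascades: list[PlantedCascade] = field(default_factory=list)
    planted_targets: list[PlantedTarget] = field(default_factory=list)
    planted_activation: PlantedActivation | None = None
    focal_gene: str = "Brca1"
    focal_partners: list[FocalPartner] = field(default_factory=list)
    protein_gene_slope: float = 0.11
    protein_gene_intercept: float = 6.0
    protein_missing_rate: float = 0.10
    n_decoy_target_pairs: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.protein_missing_rate <= 1.0):
            raise UsageError("protein_missing_rate must be in [0, 1]")
        for p in self.planted_de:
            if not np.isfinite(p.effect):
                raise UsageError(f"non-finite planted effect for {p.molecule}")
        for t in self.planted_targets:
            unknown = set(t.dbs) - set(TARGET_DB_DIALECTS)
            if unknown:
                raise UsageError(f"unknown target databases {sorted(unknown)}")
            if not t.dbs:
                raise UsageError(f"planted pair {t.mirna}->{t.gene} has empty db set")


@dataclass
class SimulatedTruth:
    """Ground-truth labels for every planted structure."""

    de: list[PlantedDE]
    cascades: list[PlantedCascade]
    targets: list[PlantedTarget]
    partners: list[FocalPartner]
    activation: PlantedActivation | None
    protein_gene_slope: float


@dataclass
class SimulatedDataset:
    mrna: ExpressionTable
    mirna: ExpressionTable
    protein: ExpressionTable
    design: SampleDesign
    target_dbs: list[TargetDBFile]
    aliases: AliasTable
    gene_sets: GeneSetCollection
    truth: SimulatedTruth


def _gene_names(config: SimulationConfig) -> list[str]:
    names = [f"Gene{i:04d}" for i in range(1, config.n_genes + 1)]
    named = [config.focal_gene] + [p.gene for p in config.focal_partners]
    if config.planted_activation:
        named += list(config.planted_activation.always_high)
        named += list(config.planted_activation.switch)
    named += [p.molecule for p in config.planted_de if p.layer in ("mrna", "protein")]
    named += [c.gene for c in config.planted_cascades]
    named += [t.gene for t in config.planted_targets]
    generated = set(names)
    seen: list[str] = []
    for n in named:
        if n not in seen and n not in generated:
            seen.append(n)
    if len(seen) > config.n_genes:
        raise UsageError("more named genes than n_genes")
    for i, n in enumerate(seen):
        names[i] = n
    if len(set(names)) != len(names):
        raise UsageError("named genes collide with generated gene ids")
    return names


def _mirna_names(config: SimulationConfig) -> list[str]:
    names = [f"miR-{i}-5p" for i in range(101, 101 + config.n_mirnas)]
    planted = []
    for t in config.planted_targets:
        if t.mirna not in planted:
            planted.append(t.mirna)
    for p in config.planted_de:
        if p.layer == "mirna" and p.molecule not in planted:
            planted.append(p.molecule)
    if len(planted) > config.n_mirnas:
        raise UsageError("more planted miRNAs than n_mirnas")
    for i, n in enumerate(planted):
        names[i] = n
    if len(set(names)) != len(names):
        raise UsageError("planted miRNAs collide with generated names")
    return names


def _sample_plan(config: SimulationConfig, layer: str, tag: str) -> SampleDesign:
    plan = {"mrna": MRNA_REPLICATES, "mirna": MIRNA_REPLICATES, "protein": PROTEIN_REPLICATES}[layer]
    design = SampleDesign()
    for group in CELL_GROUPS:
        for i in range(1, plan[group] + 1):
            design.add(f"{group}_{tag}{i}", group[0], group[1])
    if config.include_tumor_groups and layer != "protein":
        for group in ("TP", "TM"):
            for i in range(1, TUMOR_REPLICATES + 1):
                design.add(f"{group}_{tag}{i}", "tumor", group)
    return design


def _layer_matrix(
    rng: np.random.Generator,
    molecule_baselines: np.ndarray,
    group_shifts: np.ndarray,
    design: SampleDesign,
    noise_sd: float,
) -> np.ndarray:
    """baseline + per-(molecule, group) shift + iid Gaussian noise."""
    groups = [design.group(s) for s in design.sample_ids]
    n_mol = molecule_baselines.size
    out = np.empty((n_mol, len(groups)))
    group_order = list(dict.fromkeys(groups))
    col_of_group = {g: i for i, g in enumerate(group_order)}
    for j, g in enumerate(groups):
        out[:, j] = molecule_baselines + group_shifts[:, col_of_group[g]]
    out += rng.normal(0.0, noise_sd, out.shape)
    return out


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate all layers, the design, target databases and ground truth."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config)
    mirnas = _mirna_names(config)
    proteins = genes[: config.n_proteins]
    if config.n_proteins > config.n_genes:
        raise UsageError("n_proteins cannot exceed n_genes")

    for p in config.planted_de:
        pool = {"mrna": genes, "mirna": mirnas, "protein": proteins}[p.layer]
        if p.molecule not in pool:
            raise UsageError(f"planted DE molecule {p.molecule!r} not in {p.layer} layer")
    for c in config.planted_cascades:
        if c.gene not in genes:
            raise UsageError(f"planted cascade gene {c.gene!r} not in mRNA layer")
        if sorted(c.sequence) != ["E", "I", "K"]:
            raise UsageError(f"cascade sequence must permute E,I,K: {c.sequence}")

    designs = {layer: _sample_plan(config, layer, tag) for layer, tag in
               (("mrna", "g"), ("mirna", "m"), ("protein", "p"))}
    merged = SampleDesign()
    for d in designs.values():
        for s, (cell, cond) in d.assignments.items():
            merged.assignments[s] = (cell, cond)

    all_groups = list(CELL_GROUPS) + (["TP", "TM"] if config.include_tumor_groups else [])
    g_idx = {g: i for i, g in enumerate(all_groups)}

    # --- per-molecule baselines (fixed draw order for determinism)
    gene_base = config.baseline_mean + rng.normal(0, config.baseline_between_sd, len(genes))
    mirna_base = config.baseline_mean + rng.normal(0, config.baseline_between_sd, len(mirnas))
    protein_base_noise = rng.normal(0, 0.5, len(proteins))

    gene_shift = np.zeros((len(genes), len(all_groups)))
    mirna_shift = np.zeros((len(mirnas), len(all_groups)))
    protein_extra = np.zeros((len(proteins), len(all_groups)))

    gene_row = {g: i for i, g in enumerate(genes)}
    mirna_row = {m: i for i, m in enumerate(mirnas)}
    protein_row = {p: i for i, p in enumerate(proteins)}

    # planted activation set overrides baselines/group levels
    act = config.planted_activation
    if act:
        for g in act.always_high:
            gene_base[gene_row[g]] = act.high_level
        for g in act.switch:
            gene_base[gene_row[g]] = act.low_level
            for grp in all_groups:
                if grp.endswith("T") and grp in CELL_GROUPS or grp in ("TP", "TM"):
                    gene_shift[gene_row[g], g_idx[grp]] += act.high_level - act.low_level

    # planted differential effects
    for p in config.planted_de:
        shift = {"mrna": gene_shift, "mirna": mirna_shift, "protein": protein_extra}[p.layer]
        row = {"mrna": gene_row, "mirna": mirna_row, "protein": protein_row}[p.layer]
        shift[row[p.molecule], g_idx[p.contrast[1]]] += p.effect

    # planted cascades: group means step up (or down) along the sequence
    for c in config.planted_cascades:
        for step, cell in enumerate(c.sequence):
            grp = cell + c.condition
            gene_shift[gene_row[c.gene], g_idx[grp]] += step * c.increment

    # miRNA suppression: targets move opposite to their planted-up miRNA
    planted_mirna_fx = {
        (p.molecule, p.contrast): p.effect for p in config.planted_de if p.layer == "mirna"
    }
    for t in config.planted_targets:
        if t.suppression == 0 or t.gene not in gene_row:
            continue
        for (m, contrast), effect in planted_mirna_fx.items():
            if m == t.mirna:
                gene_shift[gene_row[t.gene], g_idx[contrast[1]]] -= t.suppression * effect

    # focal-gene correlation partners handled after sampling (see below)
    mrna_values = _layer_matrix(rng, gene_base, gene_shift, designs["mrna"], config.noise_sd)
    mirna_values = _layer_matrix(rng, mirna_base, mirna_shift, designs["mirna"], config.noise_sd)

    mrna = ExpressionTable(
        pd.DataFrame(mrna_values, index=genes, columns=designs["mrna"].sample_ids), "mrna"
    )
    focal_vec = mrna.data.loc[config.focal_gene].to_numpy()
    fc = focal_vec - focal_vec.mean()
    f_sd = fc.std()
    for partner in config.focal_partners:
        r = partner.correlation
        if not (-1.0 <= r <= 1.0):
            raise UsageError(f"partner correlation out of range: {partner}")
        base = gene_base[gene_row[partner.gene]]
        noise = rng.normal(0, 1, focal_vec.size)
        noise -= noise.mean()
        # mix centered focal signal with orthogonalized noise at the target r
        noise -= (noise @ fc) / (fc @ fc) * fc
        noise /= noise.std() if noise.std() > 0 else 1.0
        vec = r * fc / f_sd + np.sqrt(max(0.0, 1 - r**2)) * noise
        mrna.data.loc[partner.gene] = base + vec * config.baseline_between_sd

    # protein layer tracks the realized mRNA group means through a linear trend
    mrna_groups = [designs["mrna"].group(s) for s in designs["mrna"].sample_ids]
    realized_mean = np.column_stack(
        [
            mrna.data.loc[:, [s for s, grp in zip(designs["mrna"].sample_ids, mrna_groups) if grp == g]]
            .mean(axis=1)
            .to_numpy()
            for g in all_groups
        ]
    )
    prot_groups = [designs["protein"].group(s) for s in designs["protein"].sample_ids]
    prot_cols = []
    for g in prot_groups:
        col = (
            config.protein_gene_intercept
            + config.protein_gene_slope * realized_mean[: len(proteins), g_idx[g]]
            + protein_base_noise
            + protein_extra[:, g_idx[g]]
        )
        prot_cols.append(col)
    protein_values = np.column_stack(prot_cols) + rng.normal(
        0, config.noise_sd, (len(proteins), len(prot_groups))
    )
    if config.protein_missing_rate > 0:
        drop = rng.random(protein_values.shape) < config.protein_missing_rate
        protein_values = np.where(drop, np.nan, protein_values)

    mirna_t = ExpressionTable(
        pd.DataFrame(mirna_values, index=mirnas, columns=designs["mirna"].sample_ids), "mirna"
    )
    protein_t = ExpressionTable(
        pd.DataFrame(protein_values, index=proteins, columns=designs["protein"].sample_ids),
        "protein",
    )

    target_dbs, aliases = _build_target_fixtures(config, rng, genes, mirnas)
    gene_sets = _build_gene_sets(config, rng, genes)

    truth = SimulatedTruth(
        de=list(config.planted_de),
        cascades=list(config.planted_cascades),
        targets=list(config.planted_targets),
        partners=list(config.focal_partners),
        activation=config.planted_activation,
        protein_gene_slope=config.protein_gene_slope,
    )
    return SimulatedDataset(
        mrna, mirna_t, protein_t, merged, target_dbs, aliases, gene_sets, truth
    )


def _build_target_fixtures(
    config: SimulationConfig,
    rng: np.random.Generator,
    genes: list[str],
    mirnas: list[str],
) -> tuple[list[TargetDBFile], AliasTable]:
    """Four database fixtures jointly containing the planted pairs, plus
    decoy pairs with random membership.  A third of the gene mentions use an
    upper-case alias and miRNA names carry the mmu- species prefix, so the
    consensus builder's standardization is exercised end to end."""
    aliases = AliasTable()
    for g in genes:
        if g.upper() != g:
            aliases.add(g.upper(), g)
        aliases.add(g, g)

    records: dict[str, list[tuple[str, str]]] = {name: [] for name in TARGET_DB_DIALECTS}
    pairs = list(config.planted_targets)
    planted_keys = {(t.mirna, t.gene) for t in pairs}
    decoys = []
    for _ in range(config.n_decoy_target_pairs):
        m = mirnas[rng.integers(len(mirnas))]
        g = genes[rng.integers(len(genes))]
        n_dbs = int(rng.integers(1, 5))
        dbs = frozenset(rng.choice(sorted(TARGET_DB_DIALECTS), size=n_dbs, replace=False))
        if (m, g) in planted_keys:  # never dilute a planted pair's membership
            continue
        planted_keys.add((m, g))  # nor let decoys overlap each other
        decoys.append(PlantedTarget(m, g, dbs))
    for t in pairs + decoys:
        use_alias = rng.random() < (1 / 3)
        gene_name = t.gene.upper() if use_alias and t.gene.upper() != t.gene else t.gene
        for db in sorted(t.dbs):
            records[db].append((f"mmu-{t.mirna}", gene_name))
    dbs_out = [TargetDBFile(name, recs) for name, recs in records.items() if recs]
    return dbs_out, aliases


def _build_gene_sets(
    config: SimulationConfig, rng: np.random.Generator, genes: list[str]
) -> GeneSetCollection:
    """A small GMT-style collection: one set concentrating the planted
    TME-up genes (for enrichment checks) plus random background sets."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    up_genes = {
        p.molecule for p in config.planted_de if p.layer == "mrna" and p.effect > 0
    }
    if up_genes:
        padding = [g for g in genes if g not in up_genes]
        pad = list(rng.choice(padding, size=min(10, len(padding)), replace=False))
        sets["TME_UP_RESPONSE"] = set(up_genes) | set(pad)
        descriptions["TME_UP_RESPONSE"] = "planted TME-up genes plus padding"
    if config.planted_activation:
        act = config.planted_activation
        sets[act.set_name] = set(act.always_high) | set(act.switch)
        descriptions[act.set_name] = "activation complex with late-switching member"
    for i in range(1, 6):
        members = set(rng.choice(genes, size=15, replace=False))
        sets[f"RANDOM_SET_{i}"] = members
        descriptions[f"RANDOM_SET_{i}"] = "random background set"
    return GeneSetCollection(sets, descriptions)


def plant_membership(
    dbs: list[TargetDBFile], mirna: str, gene: str, members: set[str]
) -> list[TargetDBFile]:
    """Add one (miRNA, gene) pair to the named subset of database fixtures.

    The pair's downstream consensus count equals ``len(members)``.
    """
    if not members:
        raise UsageError("membership subset must be non-empty")
    unknown = members - set(TARGET_DB_DIALECTS)
    if unknown:
        raise UsageError(f"unknown database names {sorted(unknown)}")
    by_name = {db.db_name: db for db in dbs}
    out = []
    for name in TARGET_DB_DIALECTS:
        db = by_name.get(name)
        if name in members:
            recs = (db.records if db else []) + [(mirna, gene)]
            out.append(TargetDBFile(name, recs))
        elif db is not None:
            out.append(db)
    return out


def study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study-like scenario: a focal gene up in all three TME
    cell types, shared down-regulated miRNAs (some targeting the focal
    gene with suppression), monotone E→I→K cascades in the TME condition,
    correlation partners, and an activation set with one switch gene."""
    contrasts = [("EC", "ET"), ("IC", "IT"), ("KC", "KT")]
    planted_de: list[PlantedDE] = []
    for ref, test in contrasts:
        planted_de.append(PlantedDE("Brca1", "mrna", (ref, test), 5.0))
    for g in ("Sp110", "Gene0050", "Gene0051", "Gene0052"):
        for ref, test in contrasts:
            planted_de.append(PlantedDE(g, "mrna", (ref, test), 5.0))
    for g in ("Gene0060", "Gene0061"):
        for ref, test in contrasts:
            planted_de.append(PlantedDE(g, "mrna", (ref, test), -5.0))
    shared_down_mirnas = ["miR-212-3p", "miR-21a-5p", "miR-146a-5p", "miR-16-5p", "miR-29a-3p"]
    # miRNAs switching off: large shifts are needed for q <= alpha at the
    # 2-replicate EC/KT groups (df = 3 caps the attainable p)
    for m in shared_down_mirnas:
        for ref, test in contrasts:
            planted_de.append(PlantedDE(m, "mirna", (ref, test), -12.0))
    planted_de.append(PlantedDE("Gene0020", "protein", ("EC", "ET"), 3.0))

    planted_targets = [
        PlantedTarget("miR-212-3p", "Brca1", frozenset(TARGET_DB_DIALECTS), suppression=0.0),
        PlantedTarget("miR-21a-5p", "Brca1", frozenset({"targetscan", "mirtarbase"})),
        PlantedTarget("miR-212-3p", "Gene0070", frozenset({"targetscan"}), suppression=0.3),
        PlantedTarget("miR-212-3p", "Gene0071", frozenset({"mirwalk", "microcosm"}), suppression=0.3),
        PlantedTarget("miR-21a-5p", "Gene0072", frozenset({"mirtarbase"}), suppression=0.3),
        # unregulated targets stay flat between ET and EC: they populate the
        # outer double ring, which keeps only |ET − EC| < 0.3 genes
        PlantedTarget("miR-212-3p", "Gene0075", frozenset({"targetscan", "mirwalk"})),
        PlantedTarget("miR-212-3p", "Gene0076", frozenset({"microcosm"})),
        PlantedTarget("miR-21a-5p", "Gene0077", frozenset({"mirtarbase", "targetscan"})),
    ]
    planted_cascades = [
        PlantedCascade("Gene0080", ("E", "I", "K"), 3.0),
        PlantedCascade("Gene0081", ("E", "I", "K"), 3.0),
        PlantedCascade("Gene0082", ("E", "K", "I"), 3.0),
    ]
    activation = PlantedActivation(
        always_high=("Msh2", "Msh6", "Mlh1", "Rad50", "Mre11a", "Nbn", "Rfc1"),
        switch=("Brca1",),
    )
    partners = [
        FocalPartner("Slurp1", 0.95),
        FocalPartner("Acnat2", 0.9),
        FocalPartner("Tpt1", -0.95),
        FocalPartner("Emd", -0.9),
        FocalPartner("Rnf167", -0.85),
    ]
    config = SimulationConfig(
        planted_de=planted_de,
        planted_targets=planted_targets,
        planted_cascades=planted_cascades,
        planted_activation=activation,
        focal_partners=partners,
        seed=seed,
    )
    return replace(config, **overrides) if overrides else config


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture file the pipeline reads; returns name → path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, table in (("mrna", ds.mrna), ("mirna", ds.mirna), ("protein", ds.protein)):
        paths[name] = outdir / f"{name}.tsv"
        write_expression_tsv(table, paths[name])
    paths["design"] = outdir / "design.tsv"
    ds.design.write_tsv(paths["design"])
    for db in ds.target_dbs:
        paths[f"targets_{db.db_name}"] = outdir / f"targets_{db.db_name}.tsv"
        write_target_db(db, paths[f"targets_{db.db_name}"])
    paths["aliases"] = outdir / "aliases.tsv"
    write_alias_table(ds.aliases, paths["aliases"])
    paths["gene_sets"] = outdir / "gene_sets.gmt"
    write_gmt(ds.gene_sets, paths["gene_sets"])
    return paths
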