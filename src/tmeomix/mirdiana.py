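"""Consensus aggregation of miRNA-target assertions over four databases.

The algorithm standardizes miRNA names (stripping miRBase species prefixes
such as ``mmu-`` or ``hsa-``) and gene names (mapping aliases to official
NCBI symbols), deduplicates pairs within each database, takes the union
across databases, and records for every (miRNA, gene) pair the set of
databases asserting it.  The cardinality of that set — the consensus count,
0..4 — measures how well-supported an interaction is; querying a gene
returns its targeting miRNAs at a chosen minimum consensus.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import AliasTable, TargetDBFile, UsageError

logger = logging.getLogger(__name__)

#: miRBase species prefixes are three letters plus a hyphen (mmu-, hsa-, rno-…)
_SPECIES_PREFIX = re.compile(r"^[a-z]{3}-", re.IGNORECASE)
_MIR_PREFIX = re.compile(r"^mir(?=[-0-9])", re.IGNORECASE)


def standardize_mirna(name: str) -> str:
    """Strip the species prefix; canonicalize a leading "mir" to "miR".

    "mmu-miR-212-3p" → "miR-212-3p"; names without a prefix (and family
    names like "let-7a-5p") pass through otherwise untouched.
    """
    if not name:
        raise UsageError("empty miRNA name")
    match = _SPECIES_PREFIX.match(name)
    stripped = name
    # "mir-"/"let-" open unprefixed miRNA names, never a species id
    if match and match.group(0).lower() not in ("mir-", "let-"):
        stripped = name[match.end() :]
    return _MIR_PREFIX.sub("miR", stripped, count=1)


class GeneStandardizer:
    """Alias → official-symbol mapping with a count of unmapped names."""

    def __init__(self, aliases: AliasTable):
        self.aliases = aliases
        self.unmapped_count = 0
        self._warned: set[str] = set()

    def __call__(self, name: str) -> str:
        official = self.aliases.get(name)
        if official is not None:
            return official
        self.unmapped_count += 1
        if name not in self._warned:
            self._warned.add(name)
            logger.warning("gene name %r has no official symbol; kept as-is", name)
        return name


def standardize_gene(name: str, aliases: AliasTable) -> str:
    """Map one gene name to its official symbol (unmapped names pass through)."""
    return GeneStandardizer(aliases)(name)


@dataclass
class ConsensusMatrix:
    """Per (miRNA, gene) pair, the set of databases asserting the pair."""

    memberships: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    db_names: tuple[str, ...] = ()

    def count(self, mirna: str, gene: str) -> int:
        return len(self.memberships.get((mirna, gene), frozenset()))

    @property
    def mirnas(self) -> list[str]:
        return sorted({m for m, _ in self.memberships})

    @property
    def genes(self) -> list[str]:
        return sorted({g for _, g in self.memberships})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"mirna": m, "gene": g, "count": len(dbs), "dbs": ",".join(sorted(dbs))}
            for (m, g), dbs in sorted(self.memberships.items())
        ]
        return pd.DataFrame(rows, columns=["mirna", "gene", "count", "dbs"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "ConsensusMatrix":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        memberships = {
            (r["mirna"], r["gene"]): frozenset(r["dbs"].split(","))
            for _, r in frame.iterrows()
        }
        dbs = sorted({d for v in memberships.values() for d in v})
        return cls(memberships, tuple(dbs))


def build_consensus(
    dbs: list[TargetDBFile], aliases: AliasTable | None = None
) -> ConsensusMatrix:
    """Standardize, deduplicate per database, and union across databases."""
    if not dbs:
        raise UsageError("at least one target database is required")
    gene_std = GeneStandardizer(aliases or AliasTable())
    memberships: dict[tuple[str, str], set[str]] = {}
    for db in dbs:
        seen: set[tuple[str, str]] = set()
        for raw_mirna, raw_gene in db.records:
            pair = (standardize_mirna(raw_mirna), gene_std(raw_gene))
            if pair in seen:  # duplicates inside one database count once
                continue
            seen.add(pair)
            memberships.setdefault(pair, set()).add(db.db_name)
    if gene_std.unmapped_count:
        logger.info("%d target-gene names lacked an official symbol", gene_std.unmapped_count)
    frozen = {pair: frozenset(v) for pair, v in memberships.items()}
    return ConsensusMatrix(frozen, tuple(sorted({d.db_name for d in dbs})))


def incidence_matrix(matrix: ConsensusMatrix, gene: str) -> pd.DataFrame:
    """Boolean miRNAs × databases incidence for one gene.

    Row sums equal the consensus counts of the gene's targeting miRNAs.
    """
    dbs = list(matrix.db_names)
    rows = {
        m: [d in memb for d in dbs]
        for (m, g), memb in sorted(matrix.memberships.items())
        if g == gene
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=dbs).astype(bool)


def mirnas_targeting(
    matrix: ConsensusMatrix, gene: str, min_consensus: int = 1
) -> list[tuple[str, int]]:
    """miRNAs targeting ``gene`` at the given minimum consensus.

    Sorted by consensus count descending, then miRNA name.  An unknown gene
    yields an empty list.
    """
    hits = [
        (m, len(memb))
        for (m, g), memb in matrix.memberships.items()
        if g == gene and len(memb) >= min_consensus
    ]
    return sorted(hits, key=lambda x: (-x[1], x[0]))
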