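"""Input/output for the standard formats the pipeline touches.

Alignments travel as FASTA, traits as TSV with a header row, tree sets as
bare Newick lists (one tree per line) or NEXUS trees blocks.  Also provides
the two small trait utilities used throughout: the allometric length->mass
conversion for the springtail subjects and the low/medium/high rate
categories used for display.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, InputError, TreeError

__all__ = [
    "SequenceAlignment",
    "TraitTable",
    "TreeSet",
    "RateCategory",
    "read_alignment",
    "write_alignment",
    "read_trait_table",
    "write_trait_table",
    "read_tree_set",
    "write_tree_set",
    "mass_from_length",
    "categorize_rate",
]

_DNA_ALPHABET = frozenset("ACGTN-")

#: Allometric coefficients for mass (ug) from body length (um),
#: W = 6.1894 * L**3.119 * 1e-9, modelled for Cryptopygus antarcticus.
_ALLOMETRY_COEF = 6.1894
_ALLOMETRY_EXP = 3.119
_ALLOMETRY_SCALE = 1e-9


@dataclass(frozen=True)
class SequenceAlignment:
    """An aligned set of per-individual DNA sequences.

    Invariants (enforced on construction): all sequences have equal, positive
    length; ids are unique and non-empty; the alphabet is {A,C,G,T,N,-}.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate ids in alignment: {dupes}")
        if any(not rid for rid in ids):
            raise AlignmentError("empty id in alignment")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        if 0 in lengths:
            raise AlignmentError("zero-length sequences")
        for rid, seq in self.records:
            bad = set(seq) - _DNA_ALPHABET
            if bad:
                raise AlignmentError(
                    f"record {rid!r} contains non-DNA symbols {sorted(bad)}"
                )

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def __len__(self) -> int:
        return len(self.records)

    def sequence(self, individual_id: str) -> str:
        for rid, seq in self.records:
            if rid == individual_id:
                return seq
        raise KeyError(individual_id)


@dataclass(frozen=True)
class TraitTable:
    """Per-individual metabolic rates with optional mass/length/population.

    Rates are mass-specific oxygen consumption in ulO2.ug^-1.hr^-1 and must
    be strictly positive; ids are unique.
    """

    data: pd.DataFrame = field(repr=False)
    #: raw simulated traits (pre-rescale) may be negative; measured
    #: metabolic rates must be strictly positive
    require_positive: bool = True

    REQUIRED = ("individual_id", "metabolic_rate")
    OPTIONAL = ("mass_ug", "length_um", "population")

    def __post_init__(self) -> None:
        df = self.data
        for col in self.REQUIRED:
            if col not in df.columns:
                raise InputError(f"trait table missing required column {col!r}")
        if df["individual_id"].duplicated().any():
            dupes = sorted(df.loc[df["individual_id"].duplicated(), "individual_id"])
            raise InputError(f"duplicate individual ids in trait table: {dupes}")
        rates = pd.to_numeric(df["metabolic_rate"], errors="coerce")
        if rates.isna().any():
            raise InputError("non-numeric metabolic_rate values")
        if self.require_positive and (rates <= 0).any():
            bad = df.loc[rates <= 0, "individual_id"].tolist()
            raise InputError(f"non-positive metabolic_rate for: {bad}")
        for col in ("mass_ug", "length_um"):
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="coerce")
                if ((vals <= 0) & vals.notna()).any():
                    raise InputError(f"non-positive {col} values")

    @property
    def ids(self) -> list[str]:
        return self.data["individual_id"].tolist()

    def __len__(self) -> int:
        return len(self.data)

    def rates(self) -> dict[str, float]:
        """Mapping individual id -> metabolic rate."""
        return dict(
            zip(self.data["individual_id"], self.data["metabolic_rate"].astype(float))
        )

    def with_rates(self, rates: dict[str, float]) -> "TraitTable":
        df = self.data.copy()
        df["metabolic_rate"] = [rates[i] for i in df["individual_id"]]
        return TraitTable(df, require_positive=self.require_positive)

    @classmethod
    def from_rates(
        cls, rates: dict[str, float], require_positive: bool = True
    ) -> "TraitTable":
        return cls(
            pd.DataFrame(
                {
                    "individual_id": list(rates.keys()),
                    "metabolic_rate": list(rates.values()),
                }
            ),
            require_positive=require_positive,
        )


@dataclass
class TreeSet:
    """An ordered posterior sample of rooted trees over one tip set.

    Branch lengths are in expected substitutions/site; zero-length branches
    are retained (never collapsed).  All trees must share the same tip-label
    set.
    """

    trees: dendropy.TreeList

    def __post_init__(self) -> None:
        if len(self.trees) == 0:
            raise TreeError("empty tree set")
        ref = self._tip_set(self.trees[0])
        for idx, tree in enumerate(self.trees):
            tips = self._tip_set(tree)
            if tips != ref:
                raise TreeError(
                    f"tree {idx} tip set differs from tree 0: "
                    f"{sorted(tips ^ ref)}"
                )
            for edge in tree.preorder_edge_iter():
                if edge.length is not None and edge.length < 0:
                    raise TreeError(f"negative branch length in tree {idx}")

    @staticmethod
    def _tip_set(tree: dendropy.Tree) -> frozenset[str]:
        return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())

    @property
    def tip_labels(self) -> list[str]:
        return sorted(self._tip_set(self.trees[0]))

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, idx: int) -> dendropy.Tree:
        return self.trees[idx]

    def __iter__(self):
        return iter(self.trees)


class RateCategory(str, enum.Enum):
    """Display category for a mass-specific metabolic rate.

    low: rate < 0.0010; medium: 0.0010 <= rate <= 0.0020; high: rate > 0.0020
    (ulO2.ug^-1.hr^-1).  Used for plotting/export only, never in statistics.
    """

    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


def read_alignment(path: str | Path) -> SequenceAlignment:
    """Read a FASTA alignment; sequences are upper-cased and validated."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise AlignmentError(f"duplicate id in FASTA: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if "U" in seq:
            raise AlignmentError(
                f"record {rec.id!r} contains 'U'; RNA is not accepted"
            )
        records.append((rec.id, seq))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return SequenceAlignment(tuple(records))


def write_alignment(alignment: SequenceAlignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in alignment.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_trait_table(path: str | Path) -> TraitTable:
    """Read a tab-separated trait table with a header row.

    Required columns: individual_id, metabolic_rate.  Optional columns
    (mass_ug, length_um, population) are kept when present; blank cells in
    optional numeric columns become missing values.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    for col in ("metabolic_rate", "mass_ug", "length_um"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "metabolic_rate" in df.columns and df["metabolic_rate"].isna().any():
        raise InputError("non-numeric or missing metabolic_rate values")
    return TraitTable(df)


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    """Write TSV; rates carry 12 significant digits (O(1e-3) values keep a
    meaningful 4th decimal)."""
    df = table.data.copy()
    for col in ("metabolic_rate", "mass_ug", "length_um"):
        if col in df.columns:
            df[col] = df[col].map(
                lambda x: "" if pd.isna(x) else f"{x:.12g}"
            )
    df.to_csv(path, sep="\t", index=False)


def _sniff_schema(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                return "nexus" if line.upper().startswith("#NEXUS") else "newick"
    raise InputError(f"empty tree file: {path}")


def read_tree_set(path: str | Path, burnin_fraction: float = 0.0) -> TreeSet:
    """Read a tree set (Newick list or NEXUS trees block) and drop burn-in.

    The first floor(burnin_fraction * N) trees are discarded, by count, and
    the remainder returned in file order.  1000 trees at burnin_fraction 0.1
    leave 900.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if not 0 <= burnin_fraction < 1:
        raise InputError(f"burnin_fraction must be in [0,1), got {burnin_fraction}")
    schema = _sniff_schema(path)
    try:
        trees = dendropy.TreeList.get(path=str(path), schema=schema)
    except Exception as exc:  # dendropy raises assorted parse errors
        raise TreeError(f"could not parse {path} as {schema}: {exc}") from exc
    if len(trees) == 0:
        raise InputError(f"no trees in {path}")
    n_drop = math.floor(burnin_fraction * len(trees))
    kept = dendropy.TreeList(trees[n_drop:], taxon_namespace=trees.taxon_namespace)
    for tree in kept:
        tree.is_rooted = True
    return TreeSet(kept)


def write_tree_set(tree_set: TreeSet, path: str | Path) -> None:
    """Write one rooted Newick string per line."""
    with open(path, "w") as fh:
        for tree in tree_set:
            fh.write(
                tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
            )


def mass_from_length(length_um: float) -> float:
    """Body mass (ug) from length (um) via the springtail allometry
    W = 6.1894 * L**3.119 * 1e-9."""
    if length_um < 0:
        raise InputError(f"negative length: {length_um}")
    return _ALLOMETRY_COEF * length_um**_ALLOMETRY_EXP * _ALLOMETRY_SCALE


def categorize_rate(rate: float) -> RateCategory:
    """Display category for a metabolic rate; boundaries are medium."""
    if rate <= 0:
        raise InputError(f"non-positive rate: {rate}")
    if rate < 0.0010:
        return RateCategory.LOW
    if rate <= 0.0020:
        return RateCategory.MEDIUM
    return RateCategory.HIGH
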