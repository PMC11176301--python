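"""Reading, validation and filtering of cell-level TCR tables.

Input tables are tab-separated rearrangement files with one row per
recovered TCR chain (one cell may contribute a TRA row, a TRB row, or
both).  A configurable *dialect* maps the file's column names onto the
canonical fields; a bundled dialect covers AIRR Rearrangement column
names.  Downstream analyses work on deduplicated :class:`Repertoire`
objects keyed by the junction amino-acid sequence (the V(D)J product
spanning the conserved cysteine to the conserved F/W).
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: genetic code used when checking junction_nt / junction_aa agreement
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(nt: str) -> str:
    """Translate an in-frame nucleotide string (stops rendered as '*')."""
    nt = nt.upper()
    return "".join(_CODON_TABLE.get(nt[i : i + 3], "X") for i in range(0, len(nt) - 2, 3))


class FormatError(ValueError):
    """Raised when an input table does not conform to its declared dialect."""


def normalize_gene(name: str | None) -> str:
    """Normalize an IMGT gene/allele name for comparison.

    Strips the allele suffix (``*01``) and whitespace and upper-cases,
    so ``"TRAV41*01 "`` compares equal to ``"trav41"``.  The original
    string should be kept for display.
    """
    if name is None:
        return ""
    return re.sub(r"\*.*$", "", str(name)).strip().upper()


@dataclass(frozen=True)
class ChainRecord:
    """One TCR chain observation in one cell."""

    cell_id: str
    donor_id: str
    locus: str  # "TRA" | "TRB"
    v_gene: str
    j_gene: str
    junction_aa: str
    junction_nt: str | None = None
    cohort: str = "other"
    group: str = "unknown"  # HC | AAb | newT1D | T1D | nonT1D_control | unknown
    cell_type: str = "unknown"  # CD4 | CD8 | unknown


@dataclass
class UniqueJunction:
    """A deduplicated junction amino-acid sequence with its aggregates."""

    junction_aa: str
    v_genes: set[str] = field(default_factory=set)
    j_genes: set[str] = field(default_factory=set)
    nt_sequences: set[str] = field(default_factory=set)
    cells_per_donor: dict[str, int] = field(default_factory=dict)

    @property
    def cell_count(self) -> int:
        return sum(self.cells_per_donor.values())

    @property
    def donor_count(self) -> int:
        return sum(1 for c in self.cells_per_donor.values() if c > 0)


@dataclass
class Repertoire:
    """Unique-junction table for one chain locus.

    ``entries`` maps junction_aa -> :class:`UniqueJunction`.  The sum of
    per-entry cell counts equals the number of contributing chain
    records.
    """

    locus: str
    entries: dict[str, UniqueJunction] = field(default_factory=dict)
    provenance: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.entries)

    def junctions(self) -> list[str]:
        return sorted(self.entries)

    def total_cells(self) -> int:
        return sum(e.cell_count for e in self.entries.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j in sorted(self.entries):
            e = self.entries[j]
            rows.append(
                {
                    "junction_aa": j,
                    "locus": self.locus,
                    "cell_count": e.cell_count,
                    "donor_count": e.donor_count,
                    "n_nt_variants": len(e.nt_sequences),
                    "v_genes": ",".join(sorted(e.v_genes)),
                    "j_genes": ",".join(sorted(e.j_genes)),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "junction_aa",
                "locus",
                "cell_count",
                "donor_count",
                "n_nt_variants",
                "v_genes",
                "j_genes",
            ],
        )


#: column-name dialects: canonical field -> file column
AIRR_DIALECT: dict[str, str] = {
    "cell_id": "cell_id",
    "donor_id": "donor_id",
    "locus": "locus",
    "v_gene": "v_call",
    "j_gene": "j_call",
    "junction_aa": "junction_aa",
    "junction_nt": "junction",
    "cohort": "cohort",
    "group": "group",
    "cell_type": "cell_type",
}

REQUIRED_FIELDS = ("donor_id", "locus", "v_gene", "j_gene", "junction_aa")
OPTIONAL_FIELDS = ("cell_id", "junction_nt", "cohort", "group", "cell_type")


def read_rearrangement_table(
    path: str | Path,
    dialect: Mapping[str, str] = AIRR_DIALECT,
    max_error_rate: float = 0.05,
) -> list[ChainRecord]:
    """Read a tab-separated rearrangement table into chain records.

    Rows with an empty junction are rejected (count logged).  Display
    gap characters ('-') inside junction strings are stripped: they are
    alignment padding, not residues.  The reader does *not* apply the
    in-frame or invariant-cell filters — see :func:`filter_in_frame`
    and :func:`filter_invariant_cells`.

    Raises :class:`FormatError` if a required column is missing, or if
    the per-row error rate exceeds ``max_error_rate``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for fld in REQUIRED_FIELDS:
        col = dialect.get(fld, fld)
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} (field {fld!r}) in {path}")

    records: list[ChainRecord] = []
    n_empty = 0
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))

        def get(fldname: str, default: str = "") -> str:
            return str(rowd.get(dialect.get(fldname, fldname), default)).strip()

        junction_aa = get("junction_aa").replace("-", "").upper()
        if not junction_aa:
            n_empty += 1
            continue
        locus = get("locus").upper()
        try:
            if locus not in ("TRA", "TRB"):
                raise ValueError(f"unrecognized locus {locus!r}")
            bad = set(junction_aa) - AA_ALPHABET - {"*"}
            if bad:
                raise ValueError(f"junction contains {sorted(bad)}")
            v_gene = get("v_gene")
            # locus/V prefix consistency (TRA<->TRAV, TRB<->TRBV)
            if v_gene and not normalize_gene(v_gene).startswith(locus + "V"):
                raise ValueError(f"V gene {v_gene!r} inconsistent with locus {locus}")
            nt = get("junction_nt") or None
            if nt is not None:
                nt = nt.upper()
                if len(nt) < 3:
                    raise ValueError("junction_nt shorter than one codon")
            records.append(
                ChainRecord(
                    cell_id=get("cell_id") or f"row{i}",
                    donor_id=get("donor_id"),
                    locus=locus,
                    v_gene=v_gene,
                    j_gene=get("j_gene"),
                    junction_aa=junction_aa,
                    junction_nt=nt,
                    cohort=get("cohort") or "other",
                    group=get("group") or "unknown",
                    cell_type=get("cell_type") or "unknown",
                )
            )
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")

    if n_empty:
        logger.info("%s: rejected %d rows with empty junction", path, n_empty)
    if errors:
        rate = len(errors) / max(len(df), 1)
        if rate > max_error_rate:
            raise FormatError(
                f"{path}: {len(errors)} unreadable rows (rate {rate:.1%} > "
                f"{max_error_rate:.1%}); first: {errors[0]}"
            )
        logger.warning("%s: skipped %d unreadable rows", path, len(errors))
    return records


def filter_in_frame(
    records: Sequence[ChainRecord], strict_anchors: bool = False
) -> tuple[list[ChainRecord], dict[str, int]]:
    """Keep records whose junction is a plausible in-frame protein product.

    A record is removed when its junction_aa contains a stop ('*'), or —
    when junction_nt is present — when the nt length is not divisible by
    3 or the translation disagrees with junction_aa.  With
    ``strict_anchors`` the junction must additionally start with 'C' and
    end with 'F' or 'W' (off by default: productive junctions with
    non-canonical anchors do occur).
    """
    kept: list[ChainRecord] = []
    removed = {"stop_codon": 0, "frame": 0, "translation_mismatch": 0, "anchors": 0}
    for rec in records:
        if "*" in rec.junction_aa:
            removed["stop_codon"] += 1
            continue
        if rec.junction_nt is not None:
            if len(rec.junction_nt) % 3 != 0:
                removed["frame"] += 1
                continue
            if translate(rec.junction_nt) != rec.junction_aa:
                removed["translation_mismatch"] += 1
                continue
        if strict_anchors and not (
            rec.junction_aa.startswith("C") and rec.junction_aa[-1] in "FW"
        ):
            removed["anchors"] += 1
            continue
        kept.append(rec)
    return kept, removed


#: invariant-chain removal rules (innate-like T cells)
INKT_JUNCTION = "CVVSDRGSTLGRLYF"
MAIT_V = "TRAV1-2"
MAIT_J = frozenset({"TRAJ33", "TRAJ20", "TRAJ12"})


def _is_in_frame(rec: ChainRecord) -> bool:
    if "*" in rec.junction_aa:
        return False
    if rec.junction_nt is not None:
        if len(rec.junction_nt) % 3 != 0:
            return False
        if translate(rec.junction_nt) != rec.junction_aa:
            return False
    return True


def filter_invariant_cells(
    records: Sequence[ChainRecord],
) -> tuple[list[ChainRecord], dict[str, list[str]]]:
    """Remove whole cells bearing iNKT or MAIT invariant TRA chains.

    A cell is removed entirely (all of its chains) when any of its
    in-frame TRA chains carries the canonical iNKT junction, or uses
    the MAIT TRAV1-2 V gene together with a TRAJ33/TRAJ20/TRAJ12 J
    gene.  Only in-frame chains can trigger removal, so this filter
    commutes with :func:`filter_in_frame`.  Returns the surviving
    records and a report listing removed cell ids per rule.
    """
    by_cell: dict[str, list[ChainRecord]] = defaultdict(list)
    for rec in records:
        by_cell[rec.cell_id].append(rec)

    report: dict[str, list[str]] = {"iNKT": [], "MAIT": []}
    kept: list[ChainRecord] = []
    for cell_id, chains in by_cell.items():
        rule = None
        for rec in chains:
            if rec.locus != "TRA" or not _is_in_frame(rec):
                continue
            if rec.junction_aa == INKT_JUNCTION:
                rule = "iNKT"
                break
            if normalize_gene(rec.v_gene) == MAIT_V and normalize_gene(rec.j_gene) in MAIT_J:
                rule = "MAIT"
                break
        if rule is None:
            kept.extend(chains)
        else:
            report[rule].append(cell_id)
    # preserve input order
    order = {id(r): i for i, r in enumerate(records)}
    kept.sort(key=lambda r: order[id(r)])
    return kept, report


def build_repertoire(
    records: Iterable[ChainRecord],
    locus: str,
    cohorts: Iterable[str] | None = None,
    provenance: tuple[str, ...] = (),
) -> Repertoire:
    """Aggregate chain records into a deduplicated unique-junction table.

    Entries are keyed by the exact junction_aa string; per-donor cell
    counts, gene sets and nt-sequence sets are aggregated.  The result
    is independent of input order.  ``cohorts`` optionally restricts
    which cohort labels contribute.
    """
    wanted = set(cohorts) if cohorts is not None else None
    rep = Repertoire(locus=locus, provenance=tuple(provenance))
    n = 0
    for rec in records:
        if rec.locus != locus:
            continue
        if wanted is not None and rec.cohort not in wanted:
            continue
        n += 1
        entry = rep.entries.get(rec.junction_aa)
        if entry is None:
            entry = rep.entries[rec.junction_aa] = UniqueJunction(rec.junction_aa)
        if rec.v_gene:
            entry.v_genes.add(rec.v_gene)
        if rec.j_gene:
            entry.j_genes.add(rec.j_gene)
        if rec.junction_nt:
            entry.nt_sequences.add(rec.junction_nt)
        entry.cells_per_donor[rec.donor_id] = entry.cells_per_donor.get(rec.donor_id, 0) + 1
    if n == 0:
        logger.warning("no %s records in scope; empty repertoire", locus)
    return rep


def write_repertoire(rep: Repertoire, path: str | Path) -> None:
    """Write the canonical repertoire TSV."""
    rep.to_frame().to_csv(path, sep="\t", index=False)


def read_repertoire(path: str | Path, locus: str | None = None) -> Repertoire:
    """Read a repertoire from either the canonical repertoire TSV or a
    cell-level rearrangement table (detected from the header)."""
    head = pd.read_csv(path, sep="\t", nrows=0)
    if "cell_count" in head.columns:
        df = pd.read_csv(path, sep="\t", dtype={"junction_aa": str})
        loci = df["locus"].unique().tolist() if "locus" in df else [locus]
        if locus is None:
            if len(loci) != 1:
                raise FormatError(f"{path}: multiple loci {loci}; pass locus explicitly")
            locus = loci[0]
        rep = Repertoire(locus=locus, provenance=(str(path),))
        sub = df[df["locus"] == locus] if "locus" in df else df
        for row in sub.itertuples(index=False):
            e = UniqueJunction(row.junction_aa)
            e.cells_per_donor["?"] = int(row.cell_count)
            if getattr(row, "v_genes", ""):
                e.v_genes = set(str(row.v_genes).split(","))
            if getattr(row, "j_genes", ""):
                e.j_genes = set(str(row.j_genes).split(","))
            rep.entries[row.junction_aa] = e
        return rep
    records = read_rearrangement_table(path)
    if locus is None:
        raise FormatError("locus required when reading a cell-level table")
    recs, _ = filter_in_frame(records)
    return build_repertoire(recs, locus, provenance=(str(path),))


def records_to_frame(records: Sequence[ChainRecord]) -> pd.DataFrame:
    """Cell-level DataFrame view of chain records (AIRR-style columns)."""
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "donor_id": r.donor_id,
                "locus": r.locus,
                "v_call": r.v_gene,
                "j_call": r.j_gene,
                "junction_aa": r.junction_aa,
                "junction": r.junction_nt or "",
                "cohort": r.cohort,
                "group": r.group,
                "cell_type": r.cell_type,
            }
            for r in records
        ]
    )
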