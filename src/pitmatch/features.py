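"""Junction sequence features: lengths, V/N/J decomposition, hydrophobicity.

Junction anatomy: the junction nucleotide sequence is the concatenation
of a (3'-trimmed) V-germline segment, non-templated N nucleotides, and a
(5'-trimmed) J-germline segment.  The IMGT junction convention is used
throughout: the junction includes both anchor residues (conserved C and
F/W), i.e. junction = CDR3 + 2 AA (6 nt).  Lengths are reported in nt;
where only the protein sequence is known, nt length is 3x the AA length.

Hydrophobicity is the Eisenberg consensus scale averaged over all
junction residues (anchors included by default; configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .io import normalize_gene

__all__ = [
    "EISENBERG",
    "FeatureRow",
    "hydrophobicity",
    "decompose_junction",
    "parse_imgt_feature_table",
    "compare_feature_distributions",
    "specificity_grouping",
]

#: Eisenberg consensus hydrophobicity scale (Eisenberg et al. 1984,
#: normalized consensus values; dimensionless).  Spans R = -2.53 to
#: I = 1.38; proline 0.12 and tyrosine 0.26.
EISENBERG: dict[str, float] = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}


def hydrophobicity(
    junction_aa: str, aggregate: str = "mean", include_anchors: bool = True
) -> float:
    """Eisenberg hydrophobicity of a junction amino-acid sequence.

    ``aggregate`` is "mean" (default; a per-residue average keeps the
    value on the residue scale, between -2.53 and 1.38) or "sum".
    With ``include_anchors=False`` the first and last residues (the
    conserved C and F/W anchors) are dropped before aggregating.
    """
    if not junction_aa:
        raise ValueError("empty junction")
    seq = junction_aa if include_anchors else junction_aa[1:-1]
    if not seq:
        raise ValueError(f"junction {junction_aa!r} too short without anchors")
    try:
        vals = [EISENBERG[ch] for ch in seq]
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {junction_aa!r}") from None
    return float(np.sum(vals)) if aggregate == "sum" else float(np.mean(vals))


def decompose_junction(
    junction_nt: str, v_germline_3prime: str, j_germline_5prime: str
) -> tuple[int, int, int]:
    """Split a junction into V-germline, N-region and J-germline lengths.

    v3 is the longest prefix of the junction matching a prefix of the V
    3' germline segment; j5 the longest suffix matching a suffix of the
    J 5' germline segment, constrained so v3 + j5 <= junction length.
    When the V and J claims overlap, the V claim wins (v3 maximized
    first).  Always conserves length: v3 + n + j5 = len(junction_nt).
    """
    jnt = junction_nt.upper()
    v = v_germline_3prime.upper()
    j = j_germline_5prime.upper()
    n = len(jnt)
    v3 = 0
    for i in range(min(n, len(v))):
        if jnt[i] != v[i]:
            break
        v3 = i + 1
    j5 = 0
    for i in range(1, min(n - v3, len(j)) + 1):
        if jnt[-i] != j[-i]:
            break
        j5 = i
    return v3, n - v3 - j5, j5


@dataclass
class FeatureRow:
    """Per-junction sequence features (lengths in nt)."""

    junction_aa: str
    locus: str
    junction_length_nt: int
    junction_length_aa: int
    cdr1_nt: int | None = None
    cdr2_nt: int | None = None
    cdr3_nt: int | None = None
    fr1_nt: int | None = None
    fr2_nt: int | None = None
    fr3_nt: int | None = None
    n_region_nt: int | None = None
    v3_nt: int | None = None
    j5_nt: int | None = None
    hydrophobicity: float | None = None


#: default column map for IMGT/HighV-QUEST-style feature tables
IMGT_COLUMNS: dict[str, str] = {
    "junction_aa": "JUNCTION (AA)",
    "locus": "locus",
    "junction_nt": "JUNCTION",
    "cdr1_nt": "CDR1-IMGT length",
    "cdr2_nt": "CDR2-IMGT length",
    "cdr3_nt": "CDR3-IMGT length",
    "fr1_nt": "FR1-IMGT length",
    "fr2_nt": "FR2-IMGT length",
    "fr3_nt": "FR3-IMGT length",
    "n_region_nt": "N-REGION length",
    "v3_nt": "V-REGION end length",
    "j5_nt": "J-REGION start length",
}


def parse_imgt_feature_table(
    path: str | Path, columns: Mapping[str, str] = IMGT_COLUMNS
) -> list[FeatureRow]:
    """Parse a HighV-QUEST-style TSV of per-chain region lengths.

    ``columns`` maps canonical field names to the file's column names;
    ``junction_aa`` and ``cdr3_nt`` are required.  The junction length
    follows the junction-with-anchors convention (CDR3 + 6 nt); when
    the file carries the junction nt sequence its length is used
    directly.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for fld in ("junction_aa", "cdr3_nt"):
        if columns.get(fld) not in df.columns:
            raise ValueError(f"{path}: missing mapped column {columns.get(fld)!r} for {fld!r}")

    def geti(row: Mapping[str, str], fld: str) -> int | None:
        col = columns.get(fld)
        if col is None or col not in row or str(row[col]).strip() == "":
            return None
        return int(float(row[col]))

    rows: list[FeatureRow] = []
    for _, r in df.iterrows():
        aa = str(r[columns["junction_aa"]]).replace("-", "").strip()
        if not aa:
            continue
        nt = str(r.get(columns.get("junction_nt", ""), "")).strip()
        cdr3 = geti(r, "cdr3_nt")
        jlen_nt = len(nt) if nt else (cdr3 + 6 if cdr3 is not None else 3 * len(aa))
        rows.append(
            FeatureRow(
                junction_aa=aa,
                locus=str(r.get(columns.get("locus", ""), "")) or "TRA",
                junction_length_nt=jlen_nt,
                junction_length_aa=len(aa),
                cdr1_nt=geti(r, "cdr1_nt"),
                cdr2_nt=geti(r, "cdr2_nt"),
                cdr3_nt=cdr3,
                fr1_nt=geti(r, "fr1_nt"),
                fr2_nt=geti(r, "fr2_nt"),
                fr3_nt=geti(r, "fr3_nt"),
                n_region_nt=geti(r, "n_region_nt"),
                v3_nt=geti(r, "v3_nt"),
                j5_nt=geti(r, "j5_nt"),
                hydrophobicity=hydrophobicity(aa) if set(aa) <= set(EISENBERG) else None,
            )
        )
    return rows


def features_to_frame(rows: Sequence[FeatureRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


def compare_feature_distributions(
    rows: pd.DataFrame,
    labels: Mapping[str, bool],
    features: Iterable[str],
    junction_col: str = "junction_aa",
) -> pd.DataFrame:
    """Two-sample KS comparison of feature distributions by match label.

    For each feature, junctions flagged True vs False in ``labels`` are
    compared with the two-sided two-sample Kolmogorov-Smirnov test
    (exact where scipy chooses so); per-group medians are reported and
    p-values are BH adjusted across the feature battery.
    """
    lab = rows[junction_col].map(lambda j: labels.get(j))
    out = []
    for feat in features:
        vals = pd.to_numeric(rows[feat], errors="coerce")
        a = vals[(lab == True) & vals.notna()].to_numpy()  # noqa: E712
        b = vals[(lab == False) & vals.notna()].to_numpy()  # noqa: E712
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"feature {feat!r}: need >= 2 observations per group")
        if np.array_equal(np.sort(a), np.sort(b)):
            d, p = 0.0, 1.0
        else:
            res = stats.ks_2samp(a, b, alternative="two-sided")
            d, p = float(res.statistic), float(res.pvalue)
        out.append(
            {
                "feature": feat,
                "n_true": len(a),
                "n_false": len(b),
                "median_true": float(np.median(a)),
                "median_false": float(np.median(b)),
                "ks_D": d,
                "p": p,
            }
        )
    df = pd.DataFrame(out)
    df["p_adj"] = bh_adjust(df["p"].tolist())
    return df


#: default column map for VDJdb-style exports
VDJDB_COLUMNS: dict[str, str] = {
    "locus": "gene",
    "v_gene": "v.segm",
    "j_gene": "j.segm",
    "cdr3_aa": "cdr3",
    "epitope": "antigen.epitope",
}


def specificity_grouping(
    records: pd.DataFrame,
    locus: str = "TRA",
    columns: Mapping[str, str] = VDJDB_COLUMNS,
) -> pd.DataFrame:
    """Group database TCR records into unique chains labeled by the
    number of distinct epitopes they recognize.

    A unique chain is (normalized V, CDR3 AA, normalized J); a chain is
    multi-specific iff it is associated with more than one distinct
    epitope.  Rows missing an epitope are excluded (count stored in
    ``df.attrs['excluded_no_epitope']``).  Locus values "TRA"/"TRB" and
    "A"/"B" are both accepted.
    """
    loc_col = columns["locus"]
    want = {locus, locus[-1]}  # "TRA" or trailing "A"
    sub = records[records[loc_col].astype(str).str.upper().isin({w.upper() for w in want})]
    epi = sub[columns["epitope"]].astype(str).str.strip()
    excluded = int((epi == "").sum())
    sub = sub[epi != ""]
    chains = pd.DataFrame(
        {
            "v_gene": sub[columns["v_gene"]].map(normalize_gene),
            "cdr3_aa": sub[columns["cdr3_aa"]].astype(str).str.strip().str.upper(),
            "j_gene": sub[columns["j_gene"]].map(normalize_gene),
            "epitope": sub[columns["epitope"]].astype(str).str.strip(),
        }
    )
    grouped = (
        chains.groupby(["v_gene", "cdr3_aa", "j_gene"])["epitope"]
        .nunique()
        .reset_index(name="n_epitopes")
    )
    grouped["multi_specific"] = grouped["n_epitopes"] > 1
    grouped["hydrophobicity"] = grouped["cdr3_aa"].map(
        lambda s: hydrophobicity(s) if set(s) <= set(EISENBERG) else np.nan
    )
    grouped["cdr3_length_aa"] = grouped["cdr3_aa"].str.len()
    grouped.attrs["excluded_no_epitope"] = excluded
    return grouped
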