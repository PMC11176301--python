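"""TCR-peptide contact residues in modeled TCR-pMHC complexes.

A TCR residue is a peptide contact when the minimum Euclidean distance
from any of its heavy atoms to any heavy atom of the bound peptide
chain is strictly below the cutoff (default 5.0 Angstrom).  Models are
consumed, never produced: structures arrive as PDB or mmCIF files with
an explicit chain-role map, and CDR/FR region annotations arrive as an
external table (no automatic CDR detection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

__all__ = [
    "ContactRecord",
    "ContactSummary",
    "load_structure",
    "contact_residues",
    "map_contacts_to_regions",
    "cdr_ratio_regression",
    "read_region_annotations",
]

CHAIN_ROLES = ("TRA", "TRB", "peptide", "MHC_alpha", "MHC_beta")
REGIONS = ("FR1", "FR2", "FR3", "CDR1", "CDR2", "CDR3", "other")


@dataclass
class ResidueAtoms:
    chain_role: str
    chain_id: str
    residue_index: int  # author numbering
    residue_aa: str
    coords: np.ndarray  # (n_heavy_atoms, 3)


@dataclass
class ContactRecord:
    model_id: str
    chain_role: str
    residue_index: int
    residue_aa: str
    region: str
    min_distance_A: float
    is_contact: bool


@dataclass
class ContactSummary:
    """Per-model contact composition."""

    model_id: str
    region_counts: dict[tuple[str, str], int] = field(default_factory=dict)  # (chain_role, region) -> n
    tra_junction_length_aa: int | None = None

    def count(self, chain_role: str, region: str) -> int:
        return self.region_counts.get((chain_role, region), 0)

    def total(self, chain_role: str) -> int:
        return sum(v for (c, _), v in self.region_counts.items() if c == chain_role)

    @property
    def cdr1_cdr3_ratio(self) -> float | None:
        """TRA CDR1 contacts / TRA CDR3 contacts; None when CDR3 has none."""
        c3 = self.count("TRA", "CDR3")
        if c3 == 0:
            return None
        return self.count("TRA", "CDR1") / c3


def load_structure(
    path: str | Path, chain_map: Mapping[str, str]
) -> dict[str, list[ResidueAtoms]]:
    """Load per-residue heavy-atom coordinates, grouped by chain role.

    ``chain_map`` assigns roles ("TRA", "TRB", "peptide", ...) to chain
    identifiers in the file.  Hydrogens are ignored.  PDB and mmCIF are
    both accepted (format sniffed by gemmi).  Raises ValueError when no
    chain is mapped to the peptide role.
    """
    for role in chain_map.values():
        if role not in CHAIN_ROLES:
            raise ValueError(f"unknown chain role {role!r}; expected one of {CHAIN_ROLES}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure {path}: {exc}") from exc
    if "peptide" not in chain_map.values():
        raise ValueError("chain_map assigns no chain to the 'peptide' role")
    out: dict[str, list[ResidueAtoms]] = {}
    model = st[0]
    seen = set()
    for chain in model:
        role = chain_map.get(chain.name)
        if role is None:
            continue
        seen.add(chain.name)
        residues = out.setdefault(role, [])
        for res in chain:
            coords = [
                (a.pos.x, a.pos.y, a.pos.z)
                for a in res
                if a.element.name != "H" and not a.name.startswith("H")
            ]
            if not coords:
                continue
            residues.append(
                ResidueAtoms(
                    chain_role=role,
                    chain_id=chain.name,
                    residue_index=res.seqid.num,
                    residue_aa=gemmi.find_tabulated_residue(res.name).one_letter_code.upper()
                    if gemmi.find_tabulated_residue(res.name)
                    else "X",
                    coords=np.asarray(coords, dtype=float),
                )
            )
    missing = set(chain_map) - seen
    if missing:
        raise ValueError(f"{path}: chains {sorted(missing)} from chain_map not found in file")
    if not out.get("peptide"):
        raise ValueError(f"{path}: peptide chain contains no heavy atoms")
    return out


def contact_residues(
    chains: Mapping[str, Sequence[ResidueAtoms]],
    cutoff_A: float = 5.0,
    model_id: str = "model",
    region_annotations: Mapping[tuple[str, int], str] | None = None,
) -> list[ContactRecord]:
    """Per-TCR-residue minimum distance to the peptide and contact flag.

    The contact criterion is a strict inequality at the cutoff: a
    residue at exactly ``cutoff_A`` is not a contact.  Only TRA and TRB
    chains are scanned.
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff must be positive")
    peptide = chains.get("peptide")
    if not peptide:
        raise ValueError("no peptide chain present")
    pep_coords = np.vstack([r.coords for r in peptide])
    records: list[ContactRecord] = []
    for role in ("TRA", "TRB"):
        for res in chains.get(role, ()):
            dmin = float(cdist(res.coords, pep_coords).min())
            region = "other"
            if region_annotations is not None:
                region = region_annotations.get((role, res.residue_index), "other")
            records.append(
                ContactRecord(
                    model_id=model_id,
                    chain_role=role,
                    residue_index=res.residue_index,
                    residue_aa=res.residue_aa,
                    region=region,
                    min_distance_A=dmin,
                    is_contact=dmin < cutoff_A,
                )
            )
    return records


def map_contacts_to_regions(
    contacts: Sequence[ContactRecord],
    region_annotations: Mapping[tuple[str, int], str] | None = None,
    tra_junction_length_aa: int | None = None,
    model_id: str | None = None,
) -> ContactSummary:
    """Aggregate contact residues into per-region counts.

    ``region_annotations`` maps (chain_role, residue_index) -> region
    label and overrides any region already attached to the records;
    unannotated contact residues fall into "other" (a warning-level
    condition, not an error).
    """
    import logging

    summary = ContactSummary(model_id=model_id or (contacts[0].model_id if contacts else "model"))
    summary.tra_junction_length_aa = tra_junction_length_aa
    n_unannotated = 0
    for rec in contacts:
        if not rec.is_contact:
            continue
        region = rec.region
        if region_annotations is not None:
            region = region_annotations.get((rec.chain_role, rec.residue_index), "other")
        if region == "other":
            n_unannotated += 1
        key = (rec.chain_role, region)
        summary.region_counts[key] = summary.region_counts.get(key, 0) + 1
    if n_unannotated:
        logging.getLogger(__name__).warning(
            "%d contact residues without region annotation mapped to 'other'", n_unannotated
        )
    return summary


def read_region_annotations(path: str | Path) -> dict[tuple[str, int], str]:
    """Read a region annotation TSV (chain, residue_index, region)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        region = str(row.region)
        if region not in REGIONS:
            raise ValueError(f"unknown region label {region!r}")
        out[(str(row.chain), int(row.residue_index))] = region
    return out


def cdr_ratio_regression(
    summaries: Sequence[ContactSummary],
) -> tuple[float, float, pd.DataFrame]:
    """OLS of the TRA CDR1:CDR3 contact ratio on TRA junction length.

    Returns (slope, p-value for H0: slope = 0, scatter table).  Models
    without a defined ratio (zero CDR3 contacts) or without a junction
    length are dropped; at least 3 usable models are required.
    """
    rows = []
    for s in summaries:
        r = s.cdr1_cdr3_ratio
        if r is None or s.tra_junction_length_aa is None:
            continue
        rows.append(
            {
                "model_id": s.model_id,
                "tra_junction_length_aa": s.tra_junction_length_aa,
                "cdr1_cdr3_ratio": r,
            }
        )
    df = pd.DataFrame(rows)
    if len(df) < 3:
        raise ValueError(f"need >= 3 models with defined ratios, got {len(df)}")
    res = stats.linregress(df["tra_junction_length_aa"], df["cdr1_cdr3_ratio"])
    p = float(res.pvalue)
    if np.isnan(p):  # zero residual variance: constant ratio
        p = 1.0 if abs(res.slope) < 1e-12 else 0.0
    return float(res.slope), p, df


def total_contact_comparison(
    summaries: Sequence[ContactSummary],
    matched: Mapping[str, bool],
    chain_role: str = "TRA",
) -> dict[str, float]:
    """Two-sided rank test of per-chain total contacts, matched vs not."""
    a = [s.total(chain_role) for s in summaries if matched.get(s.model_id) is True]
    b = [s.total(chain_role) for s in summaries if matched.get(s.model_id) is False]
    if not a or not b:
        raise ValueError("need summaries in both classes")
    p = 1.0 if sorted(a) == sorted(b) else float(
        stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    )
    return {
        "median_matched": float(np.median(a)),
        "median_nonmatched": float(np.median(b)),
        "p": p,
    }


def contacts_to_frame(records: Sequence[ContactRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
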