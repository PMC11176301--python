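"""Synthetic TCR repertoires, feature tables and structure fixtures.

The generator emulates the shape of the data the pipeline consumes:
multi-donor single-cell repertoires produced by V(D)J recombination
(V-segment 3' trimming, non-templated N insertion, J-segment 5'
trimming), clonal expansion, cross-repertoire junction sharing at edit
distance 0 or 1, and nucleotide-level convergence.  Every planted
parameter is recorded in a sidecar truth table so each pipeline stage
can be tested against known ground truth without any downloads.

It is a test harness, not a biologically calibrated recombination
model: there is no thymic selection and gene-usage priors are uniform
unless configured.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import translate, _CODON_TABLE

__all__ = [
    "SimConfig",
    "Germline",
    "simulate_germline_reference",
    "simulate_repertoire",
    "simulate_pit_reference",
    "simulate_structure_fixture",
    "write_germline_fasta",
    "read_germline_fasta",
]

_STOP_FREE_CODONS = sorted(c for c, aa in _CODON_TABLE.items() if aa != "*")
_AA_TO_CODONS: dict[str, list[str]] = {}
for _c, _aa in _CODON_TABLE.items():
    if _aa != "*":
        _AA_TO_CODONS.setdefault(_aa, []).append(_c)
for _aa in _AA_TO_CODONS:
    _AA_TO_CODONS[_aa].sort()

AA20 = sorted(_AA_TO_CODONS)

#: fixed toy D segment inserted between the two N regions of TRB junctions
TRB_D_SEGMENT = "GGGACA"


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one simulated repertoire.

    Defaults approximate the scale of a multi-donor single-cell IAR
    repertoire: a dozen donors, tens of clones per donor, a geometric
    clone-size distribution with mean ~1.3 cells (roughly a quarter of
    cells in expanded clones), mean N-insertion length of 4 nt for TRA
    and 7 nt for TRB (TRB junctions carry more non-templated
    nucleotides), and a ~1% nucleotide convergence rate.
    """

    seed: int = 0
    n_donors: int = 12
    clones_per_donor: int = 80
    locus: str = "TRA"
    cohort: str = "IAR_cohort1"
    v_usage: tuple[float, ...] | None = None  # categorical weights over V genes
    j_usage: tuple[float, ...] | None = None
    v_trim_max: int = 6  # 3' trim, uniform on 0..max, nt
    j_trim_max: int = 6  # 5' trim
    n_insert_mean: float = 4.0  # Poisson mean, nt (use ~7 for TRB)
    clone_size_mean: float = 1.3  # geometric distribution over 1,2,...
    shared_fraction_lv0: float = 0.0  # P(clone junction copied from a reference)
    convergence_rate: float = 0.01  # P(clone carries a second synonymous nt variant)
    groups: tuple[tuple[str, float], ...] = (
        ("HC", 0.25), ("AAb", 0.25), ("newT1D", 0.25), ("T1D", 0.25),
    )

    def __post_init__(self) -> None:
        for p in (self.shared_fraction_lv0, self.convergence_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.clone_size_mean < 1.0:
            raise ValueError("clone_size_mean must be >= 1")


@dataclass
class Germline:
    """Toy germline reference: junction-overlapping V 3' and J 5' segments."""

    v_segments: dict[str, dict[str, str]]  # locus -> {gene: nt}
    j_segments: dict[str, dict[str, str]]

    def v_names(self, locus: str) -> list[str]:
        return sorted(self.v_segments[locus])

    def j_names(self, locus: str) -> list[str]:
        return sorted(self.j_segments[locus])


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_STOP_FREE_CODONS) for _ in range(n))


def simulate_germline_reference(seed: int, n_v: int = 8, n_j: int = 6) -> Germline:
    """Deterministic toy V/J segment sets for both loci.

    Each V 3' segment begins with the conserved cysteine codon (TGT) and
    each J 5' segment ends with a phenylalanine codon (TTC), so that
    untrimmed in-frame junctions carry the canonical C...F anchors.
    Segments are stop-free in the junction-overlap window.
    """
    rng = np.random.default_rng(seed)
    v_segments: dict[str, dict[str, str]] = {}
    j_segments: dict[str, dict[str, str]] = {}
    for locus in ("TRA", "TRB"):
        vs = {}
        for i in range(1, n_v + 1):
            vs[f"{locus}V{i}"] = "TGT" + _random_codons(rng, int(rng.integers(4, 7)))
        js = {}
        for i in range(1, n_j + 1):
            js[f"{locus}J{i}"] = _random_codons(rng, int(rng.integers(4, 7))) + "TTC"
        v_segments[locus] = vs
        j_segments[locus] = js
    return Germline(v_segments=v_segments, j_segments=j_segments)


def write_germline_fasta(germline: Germline, path: str | Path) -> None:
    """Write segments as FASTA (id = gene name, description = segment role)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for locus in sorted(germline.v_segments):
        for name, nt in sorted(germline.v_segments[locus].items()):
            records.append(SeqRecord(Seq(nt), id=name, description=f"{locus} V 3prime"))
        for name, nt in sorted(germline.j_segments[locus].items()):
            records.append(SeqRecord(Seq(nt), id=name, description=f"{locus} J 5prime"))
    with open(path, "w") as fh:
        seqio_write(records, fh, "fasta")


def read_germline_fasta(path: str | Path) -> Germline:
    from Bio import SeqIO

    v_segments: dict[str, dict[str, str]] = {"TRA": {}, "TRB": {}}
    j_segments: dict[str, dict[str, str]] = {"TRA": {}, "TRB": {}}
    for rec in SeqIO.parse(str(path), "fasta"):
        locus = rec.id[:3]
        kind = rec.id[3]
        (v_segments if kind == "V" else j_segments)[locus][rec.id] = str(rec.seq)
    return Germline(v_segments=v_segments, j_segments=j_segments)


def _sample_junction(
    rng: np.random.Generator, cfg: SimConfig, germline: Germline
) -> dict:
    """Draw one in-frame, stop-free junction; out-of-frame draws are
    resampled so requested repertoire sizes stay exact."""
    locus = cfg.locus
    v_names = germline.v_names(locus)
    j_names = germline.j_names(locus)
    for _ in range(1000):
        v = v_names[rng.choice(len(v_names), p=cfg.v_usage)]
        j = j_names[rng.choice(len(j_names), p=cfg.j_usage)]
        v_nt = germline.v_segments[locus][v]
        j_nt = germline.j_segments[locus][j]
        v_trim = int(rng.integers(0, min(cfg.v_trim_max, len(v_nt) - 3) + 1))
        j_trim = int(rng.integers(0, min(cfg.j_trim_max, len(j_nt) - 3) + 1))
        v_part = v_nt[: len(v_nt) - v_trim]
        j_part = j_nt[j_trim:]
        n_len = int(rng.poisson(cfg.n_insert_mean))
        n_nt = "".join(rng.choice(["A", "C", "G", "T"]) for _ in range(n_len))
        if locus == "TRB":
            n2_len = int(rng.poisson(cfg.n_insert_mean / 2))
            n2 = "".join(rng.choice(["A", "C", "G", "T"]) for _ in range(n2_len))
            insert = n_nt + TRB_D_SEGMENT + n2
        else:
            insert = n_nt
        junction_nt = v_part + insert + j_part
        if len(junction_nt) % 3 != 0:
            continue
        aa = translate(junction_nt)
        if "*" in aa:
            continue
        return {
            "v_gene": v,
            "j_gene": j,
            "junction_nt": junction_nt,
            "junction_aa": aa,
            "v3_nt": len(v_part),
            "n_region_nt": len(insert),
            "j5_nt": len(j_part),
        }
    raise RuntimeError("could not draw an in-frame junction; check trim/segment config")


def _reverse_translate(rng: np.random.Generator, aa: str) -> str:
    return "".join(rng.choice(_AA_TO_CODONS[ch]) for ch in aa)


def _synonymous_variant(rng: np.random.Generator, nt: str) -> str | None:
    """A distinct nt sequence translating identically, if one exists."""
    order = rng.permutation(len(nt) // 3)
    for ci in order:
        codon = nt[3 * ci : 3 * ci + 3]
        aa = _CODON_TABLE.get(codon)
        alts = [c for c in _AA_TO_CODONS.get(aa, []) if c != codon]
        if alts:
            alt = alts[int(rng.integers(len(alts)))]
            return nt[: 3 * ci] + alt + nt[3 * ci + 3 :]
    return None


def _geometric_size(rng: np.random.Generator, mean: float) -> int:
    if mean <= 1.0:
        return 1
    return int(rng.geometric(1.0 / mean))


def simulate_repertoire(
    cfg: SimConfig,
    germline: Germline,
    reference_junctions: Sequence[str] | None = None,
    with_paired_trb: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cell-level repertoire table plus its truth table.

    Returns (cells, truth).  ``cells`` is an AIRR-style frame (cell_id,
    donor_id, locus, v_call, j_call, junction_aa, junction, cohort,
    group, cell_type) with one row per chain; each cell carries a
    ``cfg.locus`` chain and, with ``with_paired_trb`` (and cfg.locus ==
    TRA), a paired TRB chain.  ``truth`` records one row per clone with
    the planted decomposition lengths, clone size, shared and
    convergent flags.

    With ``reference_junctions`` given, each clone's junction is copied
    verbatim from the reference with probability
    ``cfg.shared_fraction_lv0`` (a planted distance-0 match; the nt
    sequence is re-drawn by reverse translation).
    """
    rng = np.random.default_rng(cfg.seed)
    group_names = [g for g, _ in cfg.groups]
    group_w = np.array([w for _, w in cfg.groups], dtype=float)
    group_w = group_w / group_w.sum()

    trb_cfg = None
    if with_paired_trb and cfg.locus == "TRA":
        trb_cfg = SimConfig(
            seed=cfg.seed,
            locus="TRB",
            n_insert_mean=max(cfg.n_insert_mean, 7.0),
            v_trim_max=cfg.v_trim_max,
            j_trim_max=cfg.j_trim_max,
        )

    cell_rows: list[dict] = []
    truth_rows: list[dict] = []
    cell_counter = 0
    for di in range(1, cfg.n_donors + 1):
        donor = f"donor{di:02d}"
        group = group_names[rng.choice(len(group_names), p=group_w)]
        for ci in range(cfg.clones_per_donor):
            shared = (
                reference_junctions is not None
                and len(reference_junctions) > 0
                and rng.random() < cfg.shared_fraction_lv0
            )
            if shared:
                aa = reference_junctions[int(rng.integers(len(reference_junctions)))]
                nt = _reverse_translate(rng, aa)
                draw = {
                    "v_gene": germline.v_names(cfg.locus)[0],
                    "j_gene": germline.j_names(cfg.locus)[0],
                    "junction_nt": nt,
                    "junction_aa": aa,
                    "v3_nt": None,
                    "n_region_nt": None,
                    "j5_nt": None,
                }
            else:
                draw = _sample_junction(rng, cfg, germline)
            size = _geometric_size(rng, cfg.clone_size_mean)
            convergent = rng.random() < cfg.convergence_rate
            if convergent:
                size = max(size, 2)
                variant = _synonymous_variant(rng, draw["junction_nt"])
                convergent = variant is not None
            trb_draw = _sample_junction(rng, trb_cfg, germline) if trb_cfg else None

            for k in range(size):
                cell_counter += 1
                cell_id = f"cell{cell_counter:06d}"
                nt_k = draw["junction_nt"]
                if convergent and k == size - 1:
                    nt_k = variant
                cell_rows.append(
                    {
                        "cell_id": cell_id,
                        "donor_id": donor,
                        "locus": cfg.locus,
                        "v_call": draw["v_gene"],
                        "j_call": draw["j_gene"],
                        "junction_aa": draw["junction_aa"],
                        "junction": nt_k,
                        "cohort": cfg.cohort,
                        "group": group,
                        "cell_type": "CD4",
                    }
                )
                if trb_draw is not None:
                    cell_rows.append(
                        {
                            "cell_id": cell_id,
                            "donor_id": donor,
                            "locus": "TRB",
                            "v_call": trb_draw["v_gene"],
                            "j_call": trb_draw["j_gene"],
                            "junction_aa": trb_draw["junction_aa"],
                            "junction": trb_draw["junction_nt"],
                            "cohort": cfg.cohort,
                            "group": group,
                            "cell_type": "CD4",
                        }
                    )
            truth_rows.append(
                {
                    "clone_id": f"{donor}_c{ci:04d}",
                    "donor_id": donor,
                    "group": group,
                    "locus": cfg.locus,
                    "junction_aa": draw["junction_aa"],
                    "junction_nt": draw["junction_nt"],
                    "v_gene": draw["v_gene"],
                    "j_gene": draw["j_gene"],
                    "v3_nt": draw["v3_nt"],
                    "n_region_nt": draw["n_region_nt"],
                    "j5_nt": draw["j5_nt"],
                    "clone_size": size,
                    "shared": shared,
                    "convergent": convergent,
                }
            )
    return pd.DataFrame(cell_rows), pd.DataFrame(truth_rows)


def simulate_pit_reference(
    cfg: SimConfig,
    iar_cells: pd.DataFrame,
    shared_fraction: float,
    mutate_rate: float,
    n_background: int = 1000,
    position_weights: Mapping[int, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a reference (PIT-like) table with planted Lv0/Lv1 overlap.

    For each unique ``cfg.locus`` junction in ``iar_cells``, the
    junction is planted into the reference verbatim with probability
    ``shared_fraction`` (a distance-0 match) or with exactly one amino
    acid substitution with probability ``mutate_rate`` (distance 1);
    otherwise it is not planted.  ``n_background`` de novo junctions
    are added.  Substitution positions (1-based) are drawn from
    ``position_weights`` (default: uniform over non-anchor positions).

    Returns (reference cells, truth) where truth records per planted
    junction its source, planted distance and substitution position.
    """
    if shared_fraction + mutate_rate > 1.0:
        raise ValueError("shared_fraction + mutate_rate must not exceed 1")
    if not len(iar_cells):
        raise ValueError("iar_cells is empty")
    rng = np.random.default_rng(cfg.seed + 1)
    germline = simulate_germline_reference(cfg.seed + 2)
    iar_junctions = sorted(
        iar_cells.loc[iar_cells["locus"] == cfg.locus, "junction_aa"].unique()
    )
    iar_set = set(iar_junctions)

    rows: list[dict] = []
    truth: list[dict] = []
    counter = 0

    def add_row(aa: str, nt: str, v: str, j: str) -> None:
        nonlocal counter
        counter += 1
        rows.append(
            {
                "cell_id": f"pit{counter:06d}",
                "donor_id": f"pitdonor{1 + counter % 7:02d}",
                "locus": cfg.locus,
                "v_call": v,
                "j_call": j,
                "junction_aa": aa,
                "junction": nt,
                "cohort": "PIT",
                "group": "nonT1D_control",
                "cell_type": "CD8",
            }
        )

    for aa in iar_junctions:
        u = rng.random()
        if u < shared_fraction:
            add_row(aa, _reverse_translate(rng, aa), germline.v_names(cfg.locus)[0], germline.j_names(cfg.locus)[0])
            truth.append({"junction_aa": aa, "planted": aa, "planted_distance": 0, "substitution_position": None})
        elif u < shared_fraction + mutate_rate:
            if position_weights:
                positions = sorted(p for p in position_weights if 1 <= p <= len(aa))
                w = np.array([position_weights[p] for p in positions], dtype=float)
                pos = int(rng.choice(positions, p=w / w.sum()))
            else:
                pos = int(rng.integers(2, len(aa)))  # spare the anchors
            mutated = None
            for _ in range(50):
                alt = AA20[int(rng.integers(len(AA20)))]
                if alt == aa[pos - 1]:
                    continue
                cand = aa[: pos - 1] + alt + aa[pos:]
                if cand not in iar_set:
                    mutated = cand
                    break
            if mutated is None:
                continue
            add_row(mutated, _reverse_translate(rng, mutated), germline.v_names(cfg.locus)[1], germline.j_names(cfg.locus)[0])
            truth.append({"junction_aa": aa, "planted": mutated, "planted_distance": 1, "substitution_position": pos})

    bg_cfg = SimConfig(seed=cfg.seed + 3, locus=cfg.locus, n_insert_mean=cfg.n_insert_mean)
    for _ in range(n_background):
        for _try in range(100):
            draw = _sample_junction(rng, bg_cfg, germline)
            if draw["junction_aa"] not in iar_set:
                break
        add_row(draw["junction_aa"], draw["junction_nt"], draw["v_gene"], draw["j_gene"])

    return pd.DataFrame(rows), pd.DataFrame(
        truth, columns=["junction_aa", "planted", "planted_distance", "substitution_position"]
    )


def simulate_structure_fixture(
    layout: Mapping[tuple[str, str], int],
    pdb_path: str | Path,
    annotation_path: str | Path | None = None,
    n_noncontact_per_region: int = 2,
    cif_path: str | Path | None = None,
) -> dict[tuple[str, int], str]:
    """Write a toy TCR-peptide complex with a known contact layout.

    ``layout`` maps (chain_role, region) -> number of residues planted
    within 5 A of the peptide chain, e.g. ``{("TRA", "CDR1"): 2,
    ("TRA", "CDR3"): 5}``.  Contact residues sit 3.0 A above a peptide
    atom; each region also receives ``n_noncontact_per_region``
    residues 30 A away.  Chains: TRA -> "A", TRB -> "B", peptide ->
    "P".  Every residue has CA and CB pseudo-atoms.  Writes PDB (and
    optionally mmCIF) plus a region-annotation TSV; returns the
    (chain_role, residue_index) -> region mapping.
    """
    import gemmi

    chain_ids = {"TRA": "A", "TRB": "B"}
    regions_order = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "other")
    n_pep = 10

    st = gemmi.Structure()
    st.name = "synthetic contact fixture"
    model = gemmi.Model("1")

    def make_residue(name: str, seqid: int, x: float, y: float, z: float) -> "gemmi.Residue":
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(seqid, " ")
        for atom_name, dz in (("CA", 0.0), ("CB", 1.5)):
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(x, y, z + dz)
            res.add_atom(atom)
        return res

    pep = gemmi.Chain("P")
    for i in range(n_pep):
        pep.add_residue(make_residue("GLY", i + 1, 3.5 * i, 0.0, 0.0))
    model.add_chain(pep)

    annotations: dict[tuple[str, int], str] = {}
    for role in ("TRA", "TRB"):
        chain = gemmi.Chain(chain_ids[role])
        seqid = 0
        for region in regions_order:
            n_contact = int(layout.get((role, region), 0))
            for k in range(n_contact):
                seqid += 1
                x = 3.5 * (seqid % n_pep)  # directly above a peptide atom
                chain.add_residue(make_residue("ALA", seqid, x, 3.0, 0.0))
                annotations[(role, seqid)] = region
            for k in range(n_noncontact_per_region if region != "other" else 0):
                seqid += 1
                chain.add_residue(make_residue("ALA", seqid, 3.5 * (seqid % n_pep), 30.0, 0.0))
                annotations[(role, seqid)] = region
        if seqid:
            model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(pdb_path))
    if cif_path is not None:
        st.make_mmcif_document().write_file(str(cif_path))
    if annotation_path is not None:
        pd.DataFrame(
            [
                {"chain": role, "residue_index": idx, "region": region}
                for (role, idx), region in sorted(annotations.items())
            ]
        ).to_csv(annotation_path, sep="\t", index=False)
    return annotations
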