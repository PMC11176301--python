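"""Worked-example human TCR junction sets.

Small curated sets of real human TCR junctions from a published
cross-sectional comparison of blood islet-antigen-reactive (IAR) CD4+
T cells with pancreas-infiltrating T cells (PIT) in type 1 diabetes.
They exercise the matching machinery on known ground truth:

* ``PERFECT_MATCH_TRA_PAIRS`` — ten IAR/PIT TRA chain pairs whose
  junctions match perfectly (edit distance 0), with their V/J genes;
* ``SINGLE_MISMATCH_TRA_PAIRS`` — IAR TRA junctions of known islet
  specificity, each paired with PIT junctions at edit distance exactly
  1 (display gap characters already stripped);
* ``MULTISPECIFIC_TRB_TRIO`` — three TRB junctions from multi-specific
  TCRs (two islet-reactive clones and one influenza-reactive clone)
  that differ pairwise at a single position, all paired with the same
  TRA chain;
* ``MATCH_COUNT_TOTALS`` — the repertoire-level match and size totals
  that accompany these examples (unique junction counts per locus and
  the perfect-match tallies against the PIT reference).
"""

from __future__ import annotations

__all__ = [
    "PERFECT_MATCH_TRA_PAIRS",
    "SINGLE_MISMATCH_TRA_PAIRS",
    "MULTISPECIFIC_TRB_TRIO",
    "MULTISPECIFIC_SHARED_TRA",
    "MATCH_COUNT_TOTALS",
]

# (iar_v, iar_junction, iar_j, pit_v, pit_junction, pit_j)
PERFECT_MATCH_TRA_PAIRS: list[tuple[str, str, str, str, str, str]] = [
    ("TRAV1-2", "CAVRMNTGFQKLVF", "TRAJ8", "TRAV1-2", "CAVRMNTGFQKLVF", "TRAJ8"),
    ("TRAV12-1", "CVVNDQAGTALIF", "TRAJ15", "TRAV12-1", "CVVNDQAGTALIF", "TRAJ15"),
    ("TRAV12-1", "CVVQGGSYIPTF", "TRAJ6", "TRAV12-1", "CVVQGGSYIPTF", "TRAJ6"),
    ("TRAV12-2", "CAVNQAGTALIF", "TRAJ15", "TRAV12-2", "CAVNQAGTALIF", "TRAJ15"),
    ("TRAV12-2", "CAVRSNFGNEKLTF", "TRAJ48", "TRAV12-2", "CAVRSNFGNEKLTF", "TRAJ48"),
    ("TRAV13-1", "CAASIGTGTASKLTF", "TRAJ44", "TRAV13-1", "CAASIGTGTASKLTF", "TRAJ44"),
    ("TRAV41", "CAASNTGNQFYF", "TRAJ49", "TRAV41", "CAASNTGNQFYF", "TRAJ49"),
    ("TRAV5", "CAERGLTGGGNKLTF", "TRAJ10", "TRAV5", "CAERGLTGGGNKLTF", "TRAJ10"),
    ("TRAV8-2", "CVVSGGSNYKLTF", "TRAJ53", "TRAV8-2", "CVVSGGSNYKLTF", "TRAJ53"),
    ("TRAV8-3", "CAVGPTGTASKLTF", "TRAJ44", "TRAV8-3", "CAVGPTGTASKLTF", "TRAJ44"),
]

# specificity -> (iar_v, iar_junction, iar_j, [(pit_v, pit_junction, pit_j), ...])
SINGLE_MISMATCH_TRA_PAIRS: dict[str, tuple[str, str, str, list[tuple[str, str, str]]]] = {
    "GADp15": (
        "TRAV41", "CAAAGNQFYF", "TRAJ49",
        [
            ("TRAV29/DV5", "CAARGNQFYF", "TRAJ49"),
            ("TRAV21", "CAAIGNQFYF", "TRAJ49"),
            ("TRAV29/DV5", "CAASAGNQFYF", "TRAJ49"),
        ],
    ),
    "IGRP39": (
        "TRAV25", "CAGQTGANNLFF", "TRAJ36",
        [
            ("TRAV16", "CALQTGANNLFF", "TRAJ36"),
            ("TRAV13-1", "CATQTGANNLFF", "TRAJ36"),
            ("TRAV24", "CASQTGANNLFF", "TRAJ36"),
        ],
    ),
    "ZNP1": (
        "TRAV13-1", "CAASGANSGYALNF", "TRAJ41",
        [("TRAV8-4", "CAVSGANSGYALNF", "TRAJ41")],
    ),
    "Multiple": (
        "TRAV29/DV5", "CAASRYSGGGADGLTF", "TRAJ45",
        [("TRAV13-1", "CAASRSSGGGADGLTF", "TRAJ45")],
    ),
    "Multiple2": (
        "TRAV23/DV6", "CAASNPDYKLSF", "TRAJ20",
        [("TRAV13-1", "CAASNNDYKLSF", "TRAJ20")],
    ),
}

#: TRB junctions of three multi-specific TCRs sharing one TRA chain
MULTISPECIFIC_TRB_TRIO: list[tuple[str, str, str, str]] = [
    ("Clone_81", "TRBV12-4", "CASSPQGGNTEAFF", "TRBJ1-1"),
    ("Clone_566", "TRBV12-4", "CASSVQGGNTEAFF", "TRBJ1-1"),
    ("P196-1", "TRBV12-4", "CASSLQGGNTEAFF", "TRBJ1-1"),
]

MULTISPECIFIC_SHARED_TRA: tuple[str, str, str] = ("TRAV29/DV5", "CAASRYSGGGADGLTF", "TRAJ45")

#: repertoire-level totals accompanying the worked examples
MATCH_COUNT_TOTALS: dict[str, int] = {
    # unique junction counts
    "iar_cohort1_unique_tra": 2174,
    "iar_cohort1_unique_trb": 2136,
    "iar_cohort2_unique_tra": 1090,
    "iar_cohort2_unique_trb": 1051,
    "iar_combined_unique_tra": 3264,
    "iar_combined_unique_trb": 3187,
    "iar_combined_unique_all": 6451,
    "pit_unique_tra": 4614,
    "pit_unique_trb": 5143,
    "pit_unique_all": 9757,
    # perfect (distance 0) matches against the pooled PIT reference
    "cohort1_perfect_tra_matches": 55,
    "cohort1_perfect_trb_matches": 7,
    "cohort2_perfect_tra_matches": 30,
    "cohort2_perfect_trb_matches": 4,
    # distance <= 1 ("PIT-matched") TRA junctions
    "cohort1_lv01_tra_matches": 582,
    "cohort2_lv01_tra_matches": 360,
    "combined_lv01_tra_matches": 942,
    # convergent junctions among combined unique IAR junctions
    "convergent_tra": 69,
    "convergent_trb": 24,
    "convergent_total": 93,
}
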