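"""End-to-end orchestration: filter -> repertoire -> match -> statistics.

``run_pipeline`` executes the full cross-sectional comparison on a query
(cell-level IAR) table and a reference (PIT) table: in-frame and
invariant-cell filtering, repertoire deduplication, edit-distance
matching, PIT-matched designation, enrichment and clonality statistics
and junction feature comparisons.  All stage outputs are written as
TSVs next to a machine-readable JSON summary, a MANIFEST marking stage
completeness, and a log echoing config and versions.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .io import (
    build_repertoire,
    filter_in_frame,
    filter_invariant_cells,
    read_rearrangement_table,
    records_to_frame,
    write_repertoire,
)
from .matching import (
    MatchConfig,
    designate_pit_matched,
    match_repertoires,
    matches_to_frame,
    pooled_reference,
)
from .enrichment import stage_contingency, donor_level_fractions, vj_usage_enrichment
from .clonality import classify_clonality, clonality_to_frame, convergence_summary
from .features import compare_feature_distributions, hydrophobicity

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Config does not validate (missing paths, bad parameters)."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    query: str
    reference: str
    outdir: str
    seed: int = 0
    max_distance: int = 1
    pooled_reference: bool = False
    bh_alpha: float = 0.05
    min_nt_for_convergence: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValidationError(str(exc)) from exc

    def validate(self) -> None:
        for name in ("query", "reference"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise ValidationError(f"{name} path does not exist: {p}")
        if not 0.0 < self.bh_alpha < 1.0:
            raise ValidationError(f"bh_alpha must be in (0,1), got {self.bh_alpha}")
        if self.max_distance < 0:
            raise ValidationError("max_distance must be >= 0")


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle; returns the summary.

    Outputs under ``cfg.outdir``: per-stage TSVs, ``summary.json``,
    ``MANIFEST`` (stage -> complete/failed), and ``run.log``.  A stage
    error aborts the run with a stage-named message; outputs of stages
    that already completed are retained.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    summary: dict[str, Any] = {
        "pitmatch_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "config": asdict(cfg),
    }

    def finish(stage: str, ok: bool = True) -> None:
        manifest[stage] = "complete" if ok else "failed"
        (outdir / "MANIFEST").write_text(
            "".join(f"{k}\t{v}\n" for k, v in manifest.items())
        )

    stage = "filter"
    try:
        q_records = read_rearrangement_table(cfg.query)
        r_records = read_rearrangement_table(cfg.reference)
        q_records, q_frame_removed = filter_in_frame(q_records)
        q_records, q_invariant = filter_invariant_cells(q_records)
        r_records, r_frame_removed = filter_in_frame(r_records)
        summary["filter"] = {
            "query_removed_in_frame": q_frame_removed,
            "query_removed_invariant": {k: len(v) for k, v in q_invariant.items()},
            "reference_removed_in_frame": r_frame_removed,
            "query_records": len(q_records),
            "reference_records": len(r_records),
        }
        records_to_frame(q_records).to_csv(outdir / "query_filtered.tsv", sep="\t", index=False)
        finish(stage)

        stage = "repertoire"
        reps = {}
        for locus in ("TRA", "TRB"):
            reps[("query", locus)] = build_repertoire(q_records, locus)
            reps[("reference", locus)] = build_repertoire(r_records, locus)
            for side in ("query", "reference"):
                rep = reps[(side, locus)]
                if len(rep):
                    write_repertoire(rep, outdir / f"{side}_{locus}_repertoire.tsv")
        summary["unique_junctions"] = {
            f"{side}_{locus}": len(reps[(side, locus)])
            for side in ("query", "reference")
            for locus in ("TRA", "TRB")
        }
        summary["unique_junctions"]["query_combined"] = (
            summary["unique_junctions"]["query_TRA"] + summary["unique_junctions"]["query_TRB"]
        )
        finish(stage)

        stage = "match"
        if cfg.pooled_reference:
            ref_tra = pooled_reference(reps[("reference", "TRA")], reps[("reference", "TRB")])
            mcfg = MatchConfig(max_distance=cfg.max_distance, cross_locus=True)
        else:
            ref_tra = reps[("reference", "TRA")]
            mcfg = MatchConfig(max_distance=cfg.max_distance)
        tra_matches = match_repertoires(reps[("query", "TRA")], ref_tra, mcfg)
        cells = records_to_frame(q_records)
        labels = designate_pit_matched(cells, tra_matches, threshold=cfg.max_distance)
        matched_flags = dict(zip(labels["junction_aa"], labels["pit_matched"]))
        matches_to_frame(tra_matches, matched_flags).to_csv(
            outdir / "tra_matches.tsv", sep="\t", index=False
        )
        labels.to_csv(outdir / "pit_matched_labels.tsv", sep="\t", index=False)
        by_locus = labels.groupby("locus")["pit_matched"].agg(["sum", "count"])
        summary["pit_matched"] = {
            locus: {"matched": int(row["sum"]), "total": int(row["count"])}
            for locus, row in by_locus.iterrows()
        }
        finish(stage)

        stage = "clonality"
        clon_frames = []
        for locus in ("TRA", "TRB"):
            rows = classify_clonality(reps[("query", locus)])
            clon_frames.append(clonality_to_frame(rows))
        clon = pd.concat(clon_frames, ignore_index=True)
        clon.to_csv(outdir / "clonality.tsv", sep="\t", index=False)
        has_nt = clon["n_nt_variants"] > 0
        summary["clonality"] = {
            "expanded": int(clon["expanded"].sum()),
            "public": int(clon["public"].sum()),
            "private": int(clon["private"].sum()),
            "converged": int(clon["converged"].sum()),
            "with_nt": int(has_nt.sum()),
        }
        if has_nt.any():
            conv = convergence_summary(
                [r for locus in ("TRA", "TRB") for r in classify_clonality(reps[("query", locus)])]
            )
            conv.to_csv(outdir / "convergence.tsv", sep="\t", index=False)
        finish(stage)

        stage = "enrichment"
        junc_meta = cells[cells["locus"].isin(["TRA"])].drop_duplicates("junction_aa")
        lab_tra = labels[labels["locus"] == "TRA"].merge(
            junc_meta[["junction_aa", "donor_id", "group"]], on="junction_aa", how="left"
        )
        expanded_map = dict(zip(clon["junction_aa"], clon["expanded"]))
        lab_tra["expanded"] = lab_tra["junction_aa"].map(expanded_map).fillna(False)
        stage_tables = []
        for stratum in ("expanded", "non-expanded"):
            tbl = stage_contingency(lab_tra, stratum=stratum)
            if len(tbl):
                tbl.insert(0, "stratum", stratum)
                stage_tables.append(tbl)
        if stage_tables:
            pd.concat(stage_tables, ignore_index=True).to_csv(
                outdir / "stage_contingency.tsv", sep="\t", index=False
            )
        per_donor, donor_tests = donor_level_fractions(lab_tra)
        per_donor.to_csv(outdir / "donor_fractions.tsv", sep="\t", index=False)
        if len(donor_tests):
            donor_tests.to_csv(outdir / "donor_tests.tsv", sep="\t", index=False)
        genes = {
            j: sorted(reps[("query", "TRA")].entries[j].v_genes)
            for j in reps[("query", "TRA")].entries
        }
        vj = vj_usage_enrichment(genes, matched_flags, alpha=cfg.bh_alpha)
        if len(vj):
            vj.to_csv(outdir / "v_usage_enrichment.tsv", sep="\t", index=False)
            summary["v_usage_significant"] = vj.loc[vj["significant"], "gene"].tolist()
        finish(stage)

        stage = "features"
        feat = pd.DataFrame(
            {
                "junction_aa": list(reps[("query", "TRA")].entries),
            }
        )
        feat["junction_length_nt"] = feat["junction_aa"].str.len() * 3
        feat["hydrophobicity"] = feat["junction_aa"].map(hydrophobicity)
        comp = compare_feature_distributions(
            feat, matched_flags, ["junction_length_nt", "hydrophobicity"]
        )
        comp.to_csv(outdir / "feature_comparisons.tsv", sep="\t", index=False)
        summary["features"] = {
            row["feature"]: {
                "median_matched": row["median_true"],
                "median_nonmatched": row["median_false"],
                "p": row["p"],
                "p_adj": row["p_adj"],
            }
            for _, row in comp.iterrows()
        }
        finish(stage)
    except Exception as exc:
        finish(stage, ok=False)
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    (outdir / "run.log").write_text(
        f"pitmatch {__version__} python {platform.python_version()}\n"
        f"seed {cfg.seed}\nconfig {asdict(cfg)}\n"
    )
    return summary
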