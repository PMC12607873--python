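"""End-to-end orchestration: simulate -> preprocess -> beta diversity ->
engraftment -> concordance, with a YAML config, per-stage TSV outputs, and a
deterministic summary JSON.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hma_fidelity import beta, concordance, engraftment, preprocess, simulate, tables

logger = logging.getLogger("hma_fidelity.pipeline")

DEFAULT_CONFIG = {
    "outdir": "results/run",
    "simulate": {
        "scenario": "default",
        "n_taxa": 100,
        "n_donors": 6,
        "n_mice": 3,
        "design": "HTR",
        "dose_percent": 5.0,
    },
    "preprocess": {
        "min_ra_percent": 0.1,
        "replicate_averaging": True,
    },
    "beta": {
        "n_permutations": 999,
        "method": "kruskal_dunn",
    },
    "engraftment": {
        "detection_threshold": 0.0,
        "min_pairs": 5,
    },
}

SCENARIOS = {
    "default": simulate.default_truth,
    "strong_filter": simulate.strong_filter_truth,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def validate_config(config: dict) -> dict:
    """Fill defaults and reject malformed configurations before any work."""
    if "seed" not in config:
        raise ValueError("config must set an explicit seed")
    merged = _merge(DEFAULT_CONFIG, config)
    seed = merged["seed"]
    if not isinstance(seed, int) or isinstance(seed, bool):
        raise ValueError(f"seed must be an integer, got {seed!r}")
    sim = merged["simulate"]
    if sim["scenario"] not in SCENARIOS:
        raise ValueError(f"unknown scenario {sim['scenario']!r}")
    if sim["design"] not in ("HTR", "MTR"):
        raise ValueError(f"unknown design {sim['design']!r}")
    for key in ("n_taxa", "n_donors", "n_mice"):
        if int(sim[key]) < 1:
            raise ValueError(f"simulate.{key} must be >= 1")
    if not 0 < float(sim["dose_percent"]) < 100:
        raise ValueError("simulate.dose_percent must lie in (0, 100)")
    if merged["preprocess"]["min_ra_percent"] < 0:
        raise ValueError("preprocess.min_ra_percent must be >= 0")
    if int(merged["beta"]["n_permutations"]) < 1:
        raise ValueError("beta.n_permutations must be >= 1")
    if merged["engraftment"]["detection_threshold"] < 0:
        raise ValueError("engraftment.detection_threshold must be >= 0")
    if int(merged["engraftment"]["min_pairs"]) < 0:
        raise ValueError("engraftment.min_pairs must be >= 0")
    return merged


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _stage(name: str, t0: float) -> None:
    logger.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Execute every stage on a synthetic cohort and write the report bundle.

    Returns the summary dictionary; all stage TSVs, the truth sidecar, the
    summary JSON and a run log are written under the output directory.
    Deterministic: identical config and seed give a byte-identical
    ``summary.json``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = validate_config(config)
    seed = cfg["seed"]
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("hma_fidelity")
    root.addHandler(handler)
    t0 = time.perf_counter()
    summary: dict = {"config": cfg}

    try:
        # --- simulate ---------------------------------------------------
        sim = cfg["simulate"]
        truth = SCENARIOS[sim["scenario"]](n_taxa=int(sim["n_taxa"]), seed=seed)
        cohort = simulate.generate_cohort(
            truth,
            n_donors=int(sim["n_donors"]),
            n_mice=int(sim["n_mice"]),
            design=sim["design"],
            dose_percent=float(sim["dose_percent"]),
            seed=seed,
        )
        tables.write_taxon_table(cohort.table, out / "abundance.tsv")
        tables.write_metadata(cohort.meta, out / "metadata.tsv")
        simulate.write_truth(
            cohort.truth, out / "truth.tsv", out / "manifest.json", cohort.manifest
        )
        summary["cohort"] = {
            "n_samples": len(cohort.table.samples),
            "n_taxa": len(cohort.table.taxa),
            "n_pairs": len(cohort.pairing.pairs),
        }
        _stage("simulate", t0)

        # --- preprocess -------------------------------------------------
        if cfg["preprocess"]["replicate_averaging"]:
            averaged = preprocess.average_replicates(cohort.table, cohort.meta)
        else:
            averaged = tables.renormalize(cohort.table)
        tables.write_taxon_table(averaged, out / "abundance_averaged.tsv")
        _stage("preprocess", t0)

        # --- beta diversity ----------------------------------------------
        meta_by_col = {m.sample_id: m for m in cohort.meta}
        for m in cohort.meta:
            if m.host == "mouse":
                meta_by_col.setdefault(m.replicate_group, m)
        hosts = [meta_by_col[c].host for c in averaged.samples]

        dist = beta.bray_curtis(averaged)
        beta.write_dist_matrix(dist, out / "bray_curtis.tsv")
        ordination = beta.pcoa(dist)
        ordination.to_frame().to_csv(out / "pcoa.tsv", sep="\t", float_format="%.10g")

        n_perm = int(cfg["beta"]["n_permutations"])
        manova = beta.permanova(dist, hosts, n_perm=n_perm, seed=seed)
        mdisp = beta.permdisp(dist, hosts, n_perm=n_perm, seed=seed)
        grouped = beta.extract_group_dissimilarities(dist, cohort.meta, cohort.pairing)
        comparable = {k: v for k, v in grouped.categories.items() if len(v) >= 2}
        group_test = beta.compare_groups(comparable, method=cfg["beta"]["method"])
        pd.DataFrame(
            [(c, v) for c, vals in grouped.categories.items() for v in vals],
            columns=["category", "dissimilarity"],
        ).to_csv(out / "grouped_dissimilarities.tsv", sep="\t", index=False,
                 float_format="%.10g")
        summary["beta_diversity"] = {
            "permanova": {
                "pseudo_F": manova.statistic,
                "r_squared": manova.r_squared,
                "p_value": manova.p_value,
                "n_permutations": manova.n_permutations,
            },
            "permdisp": {
                "pseudo_F": mdisp.statistic,
                "p_value": mdisp.p_value,
                "n_permutations": mdisp.n_permutations,
            },
            "mean_dissimilarity": grouped.means(),
            "group_test": {
                "method": group_test.method,
                "statistic": group_test.statistic,
                "p_value": group_test.p_value,
                "pairwise": {f"{a}|{b}": p for (a, b), p in group_test.pairwise.items()},
            },
            "pcoa_proportion_explained": [
                float(v) for v in ordination.proportion_explained[:3]
            ],
        }
        _stage("beta_diversity", t0)

        # --- engraftment ---------------------------------------------------
        ecfg = cfg["engraftment"]
        presence = engraftment.presence_matrix(
            cohort.table, float(ecfg["detection_threshold"])
        )
        etable = engraftment.percent_engraftment(
            presence, cohort.pairing, study_id=sim["scenario"]
        )
        engraftment.write_engraftment_table(etable, out / "engraftment.tsv")
        plotted = engraftment.filter_engrafters(etable, int(ecfg["min_pairs"]))
        stratified = engraftment.stratify_engrafters([etable])
        fractions = engraftment.donor_engraftment_fraction(presence, cohort.pairing)
        fractions.rename_axis("donor").to_csv(
            out / "donor_engraftment_fraction.tsv", sep="\t", float_format="%.10g"
        )
        mouse_cols = [
            c for c in averaged.samples if meta_by_col[c].host == "mouse"
        ]
        mouse_avg = tables.TaxonTable(averaged.data[mouse_cols], rank=averaged.rank)
        corr_stats = engraftment.engraftment_abundance_correlation(plotted, mouse_avg)
        summary["engraftment"] = {
            "n_taxa_with_denominator": int(len(etable)),
            "n_taxa_plotted": int(len(plotted)),
            "mean_percent_engraftment": float(etable["percent_engraftment"].mean()),
            "strata_counts": {
                s: int((stratified["stratum"] == s).sum())
                for s in engraftment.STRATA
            },
            "donor_fraction_min": float(fractions.min()),
            "donor_fraction_max": float(fractions.max()),
            "donor_fraction_mean": float(fractions.mean()),
            "abundance_correlation": {
                "r": corr_stats[0], "p_value": corr_stats[1], "n": corr_stats[2],
            },
        }
        _stage("engraftment", t0)

        # --- concordance ---------------------------------------------------
        deltas = concordance.delta_ra(averaged, cohort.meta, "T0", "T2")
        human_cols = [c for c in deltas.columns if c.startswith("human:")]
        mouse_delta_cols = [c for c in deltas.columns if c.startswith("mouse:")]
        summary["concordance"] = {}
        if human_cols and mouse_delta_cols:
            human_avg_cols = [
                c for c in averaged.samples if meta_by_col[c].host == "human"
            ]
            present_human = averaged.data[human_avg_cols].gt(0).any(axis=1)
            present_mouse = averaged.data[mouse_cols].gt(0).any(axis=1)
            overlap = averaged.data.index[present_human & present_mouse]
            conc = concordance.delta_concordance(
                deltas.loc[overlap, human_cols].mean(axis=1),
                deltas.loc[overlap, mouse_delta_cols].mean(axis=1),
            )
            pd.DataFrame({
                "donor_delta": conc.donor_delta,
                "recipient_delta": conc.recipient_delta,
            }).rename_axis("taxon").to_csv(
                out / "delta_concordance.tsv", sep="\t", float_format="%.10g"
            )
            summary["concordance"]["delta"] = {
                "pearson_r": conc.pearson_r,
                "p_value": conc.p_value,
                "n_taxa": len(conc.taxa),
                "quadrant_fractions": conc.quadrant_fractions,
            }

        corr = concordance.sample_correlation_matrix([averaged])
        corr.r_frame().to_csv(out / "correlation_matrix.tsv", sep="\t",
                              float_format="%.10g")
        csummary = concordance.group_correlation_summary(corr, cohort.meta)
        summary["concordance"]["correlation"] = {
            "mean_r": csummary.mean_r,
            "mean_z": csummary.mean_z,
            "z_test": None if csummary.test is None else {
                "method": csummary.test.method,
                "statistic": csummary.test.statistic,
                "p_value": csummary.test.p_value,
            },
        }
        _stage("concordance", t0)

        summary_path = out / "summary.json"
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, allow_nan=False,
                      default=_json_default)
        logger.info("wrote %s", summary_path)
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()


def _json_default(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    raise TypeError(f"not JSON serializable: {type(value)}")
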