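"""End-to-end orchestration: cohort -> normative Z-scores -> statistics.

:func:`run_full_pipeline` executes the full analysis on a (synthetic or
ingested) cohort table: inclusion filtering with group-specific scan windows,
cerebral-oxygen-delivery computation, normative GP fits for both covariate
models over the requested regions, cross-validated reference Z-scores,
group and subgroup comparisons with Benjamini–Hochberg correction within
each model's family, the CDO2 association, an STBV ANCOVA, and outcome
associations. Identical configuration and seed reproduce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ngio
from .normative import fit_normative, reference_z_scores
from .physiology import add_cdo2_column
from .stats import (
    ancova_group_test,
    bh_fdr,
    normality_screen,
    partial_spearman,
    pearson_corr,
    welch_ttest,
)
from .synthetic import REGIONS, CohortSpec, apply_inclusion_filters, generate_cohort

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ResultsBundle",
    "run_full_pipeline",
    "outcome_association",
    "type_one_error_rate",
    "config_hash",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Deterministic configuration of one full analysis run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    cohort_csv: str | None = None  # ingest instead of simulate when set
    regions: tuple = REGIONS
    k_folds: int = 5
    restarts: int = 2
    seed: int = 0
    clinical_pma_window: tuple[float, float] = (36.0, 46.0)
    reference_pma_window: tuple[float, float] = (37.0, 45.0)
    reference_ga_min: float = 37.0
    clinical_ga_min: float = 0.0
    outcome_ga_min: float = 37.0  # preterm exclusion for outcome associations

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(cfg: PipelineConfig) -> str:
    blob = repr(sorted(cfg.to_dict().items())).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ResultsBundle:
    """All tables produced by one run, plus provenance."""

    cohort: pd.DataFrame
    z_scores: pd.DataFrame  # long: subject_id, group, region, model, z
    group_tests: pd.DataFrame
    subgroup_tests: pd.DataFrame
    cdo2_tests: pd.DataFrame
    stbv_test: pd.DataFrame
    outcome_tests: pd.DataFrame
    provenance: dict

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for df in (
            self.cohort,
            self.z_scores,
            self.group_tests,
            self.subgroup_tests,
            self.cdo2_tests,
            self.stbv_test,
            self.outcome_tests,
        ):
            h.update(df.to_csv(index=False).encode())
        return h.hexdigest()

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in (
            "cohort",
            "z_scores",
            "group_tests",
            "subgroup_tests",
            "cdo2_tests",
            "stbv_test",
            "outcome_tests",
        ):
            ngio.write_cohort_csv(getattr(self, name), outdir / f"{name}.csv", self.provenance)
        ngio.write_config_yaml(self.provenance, outdir / "provenance.yaml")


def _result_row(res, **extra) -> dict:
    row = {
        "name": res.name,
        "statistic": res.statistic,
        "df": str(res.df),
        "p_raw": res.p_raw,
        "p_fdr": res.p_fdr,
    }
    row.update(extra)
    return row


def run_full_pipeline(cfg: PipelineConfig) -> ResultsBundle:
    t0 = time.time()
    if cfg.cohort_csv is not None:
        cohort = ngio.read_cohort_csv(cfg.cohort_csv)
        log.info("ingest: %d rows from %s", len(cohort), cfg.cohort_csv)
    else:
        cohort = generate_cohort(cfg.cohort)
        log.info("simulate: %d rows", len(cohort))

    ref = apply_inclusion_filters(
        cohort[cohort["group"] == "reference"], cfg.reference_pma_window, cfg.reference_ga_min
    )
    clin = apply_inclusion_filters(
        cohort[cohort["group"] == "clinical"], cfg.clinical_pma_window, cfg.clinical_ga_min
    )
    log.info("inclusion: %d reference, %d clinical retained", len(ref), len(clin))
    cohort = pd.concat([ref, clin], ignore_index=True)
    cohort = add_cdo2_column(cohort)

    # normality screen on the raw whole-brain GI (logged, never gating)
    for grp, sub in cohort.groupby("group"):
        if 3 <= len(sub) <= 5000:
            sw = normality_screen(sub["gi_whole_brain"])
            log.info("Shapiro-Wilk gi_whole_brain (%s): W=%.4f p=%.3g", grp, sw.statistic, sw.p_raw)

    # --- normative Z-scores -------------------------------------------------
    z_rows = []
    t_rows = {1: [], 2: []}
    for region in cfg.regions:
        target = f"gi_{region}"
        for model in (1, 2):
            zr = reference_z_scores(
                ref, target=target, model=model,
                k_folds=cfg.k_folds, seed=cfg.seed, restarts=cfg.restarts,
            )
            res = fit_normative(ref, target=target, model=model,
                                seed=cfg.seed, restarts=cfg.restarts)
            zc = res.z_scores(clin)
            for sid, g, z in zip(ref["subject_id"], ref["group"], zr):
                z_rows.append((sid, g, "", region, model, z))
            for sid, g, sg, z in zip(clin["subject_id"], clin["group"], clin["subgroup"], zc):
                z_rows.append((sid, g, sg, region, model, z))
            tt = welch_ttest(zc, zr[np.isfinite(zr)], name=f"{region}_model{model}")
            t_rows[model].append(
                _result_row(tt, region=region, model=model,
                            mean_z_clinical=float(np.mean(zc)),
                            mean_z_reference=float(np.nanmean(zr)))
            )
        log.info("region %s: models fitted (%.1fs elapsed)", region, time.time() - t0)

    z_scores = pd.DataFrame(
        z_rows, columns=["subject_id", "group", "subgroup", "region", "model", "z"]
    )

    # BH-FDR within each model's family of regional comparisons
    group_tests = []
    for model in (1, 2):
        fam = pd.DataFrame(t_rows[model])
        fam["p_fdr"] = bh_fdr(fam["p_raw"].to_numpy())
        group_tests.append(fam)
    group_tests = pd.concat(group_tests, ignore_index=True)

    # --- subgroup comparisons (whole brain), family of three per model -----
    sub_rows = []
    wb = z_scores[z_scores["region"] == "whole_brain"]
    for model in (1, 2):
        zm = wb[wb["model"] == model]
        zr = zm[zm["group"] == "reference"]["z"].dropna().to_numpy()
        fam = []
        for sg in ("abnormal_streaming", "left_sided", "right_sided"):
            zs = zm[zm["subgroup"] == sg]["z"].to_numpy()
            if len(zs) >= 2:
                tt = welch_ttest(zs, zr, name=f"{sg}_model{model}")
                fam.append(_result_row(tt, subgroup=sg, model=model,
                                       mean_z=float(zs.mean()), n=len(zs)))
        if fam:
            famdf = pd.DataFrame(fam)
            famdf["p_fdr"] = bh_fdr(famdf["p_raw"].to_numpy())
            sub_rows.append(famdf)
    subgroup_tests = (
        pd.concat(sub_rows, ignore_index=True) if sub_rows else pd.DataFrame()
    )

    # --- CDO2 association (clinical, complete cases) ------------------------
    cdo2_rows = []
    clin_cdo2 = cohort[cohort["group"] == "clinical"][
        ["subject_id", "cdo2", "pma_scan", "pna_days", "sex"]
    ].dropna()
    for model in (1, 2):
        zm = wb[(wb["model"] == model) & (wb["group"] == "clinical")][["subject_id", "z"]]
        merged = clin_cdo2.merge(zm, on="subject_id")
        if len(merged) >= 3:
            pr = pearson_corr(merged["z"], merged["cdo2"], name=f"cdo2_pearson_model{model}")
            cdo2_rows.append(_result_row(pr, model=model, kind="pearson",
                                         r_squared=pr.effect["r_squared"], n=len(merged)))
            ps = partial_spearman(
                merged["z"], merged["cdo2"],
                merged[["pma_scan", "pna_days", "sex"]].to_numpy(),
                name=f"cdo2_partial_spearman_model{model}",
            )
            cdo2_rows.append(_result_row(ps, model=model, kind="partial_spearman",
                                         r_squared=ps.statistic**2, n=len(merged)))
    cdo2_tests = pd.DataFrame(cdo2_rows)

    # ANCOVA: STBV between groups, adjusting for PMA, PNA and sex
    stbv = ancova_group_test(cohort, "stbv", "group", ["pma_scan", "pna_days", "sex"],
                             name="stbv_ancova")
    stbv_test = pd.DataFrame([_result_row(stbv)])
    # ANCOVA: CDO2 between cardiac subgroups, PMA as covariate
    clin_only = cohort[(cohort["group"] == "clinical") & cohort["cdo2"].notna()]
    if clin_only["subgroup"].nunique() >= 2 and len(clin_only) > 5:
        cd = ancova_group_test(clin_only, "cdo2", "subgroup", ["pma_scan"],
                               name="cdo2_subgroup_ancova")
        stbv_test = pd.concat(
            [stbv_test, pd.DataFrame([_result_row(cd)])], ignore_index=True
        )

    outcome_tests = outcome_association(z_scores, cohort, ga_min=cfg.outcome_ga_min)

    provenance = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "n_reference": int(len(ref)),
        "n_clinical": int(len(clin)),
    }
    log.info("pipeline done in %.1fs", time.time() - t0)
    return ResultsBundle(
        cohort=cohort,
        z_scores=z_scores,
        group_tests=group_tests,
        subgroup_tests=subgroup_tests,
        cdo2_tests=cdo2_tests,
        stbv_test=stbv_test,
        outcome_tests=outcome_tests,
        provenance=provenance,
    )


def outcome_association(
    z_scores: pd.DataFrame, cohort: pd.DataFrame, ga_min: float = 37.0
) -> pd.DataFrame:
    """Partial Spearman associations of whole-brain Z with outcome scores.

    Clinical subjects only; excludes preterm (GA < `ga_min`) and confirmed
    genetic diagnoses. Bayley cognitive and motor composites are adjusted for
    deprivation rank (IMD); autism-trait scores additionally for age at
    assessment. Complete-case analysis throughout.
    """
    needed = ["cognitive", "motor", "qchat", "imd_rank", "age_assessment_months"]
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks outcome columns {missing}")
    clin = cohort[
        (cohort["group"] == "clinical")
        & (cohort["ga_birth"] >= ga_min)
        & (cohort["genetic_dx"] == 0)
    ]
    wb = z_scores[(z_scores["region"] == "whole_brain") & (z_scores["group"] == "clinical")]
    rows = []
    for model in (1, 2):
        zm = wb[wb["model"] == model][["subject_id", "z"]]
        merged = clin.merge(zm, on="subject_id")
        specs = [
            ("cognitive", ["imd_rank"]),
            ("motor", ["imd_rank"]),
            ("qchat", ["imd_rank", "age_assessment_months"]),
        ]
        for outcome, covs in specs:
            sub = merged[["z", outcome, *covs]].dropna()
            if len(sub) < len(covs) + 3 + 7:
                continue
            res = partial_spearman(
                sub["z"], sub[outcome], sub[covs].to_numpy(),
                name=f"{outcome}_model{model}",
            )
            rows.append(_result_row(res, outcome=outcome, model=model, n=len(sub)))
    return pd.DataFrame(rows)


def type_one_error_rate(
    n_reps: int = 200,
    seed: int = 0,
    n_reference: int = 200,
    n_clinical: int = 33,
    alpha: float = 0.05,
    k_folds: int = 3,
    restarts: int = 1,
    model: int = 1,
) -> float:
    """End-to-end false-positive rate of the whole-brain group comparison.

    Each rep simulates a null cohort (no deficit, demographically exchangeable
    groups), fits the normative model, scores both groups (reference by k-fold
    CV) and runs the Welch test; returns the fraction of reps with p < alpha.

    Per-rep sizes are reduced relative to the headline analysis to keep the
    Monte-Carlo tractable, and the clinical group is kept small relative to
    the reference: the z-based group t-test ignores the normative model's own
    estimation error, which is shared across the scored subjects, so the test
    is only near-nominal when that shared error (variance ~1/n_reference) is
    negligible against the group-mean variance (~1/n_clinical). At comparable
    group sizes the same Monte-Carlo shows materially inflated rejection
    rates — an intrinsic property of deviation-score group comparisons worth
    bearing in mind when interpreting such tests.
    """
    rng = np.random.SeedSequence(seed)
    seeds = rng.generate_state(n_reps) % (2**31)
    hits = 0
    for s in seeds:
        spec = CohortSpec(
            n_reference=n_reference, n_clinical=n_clinical,
            seed=int(s), deficit_mode="none",
        )
        cohort = generate_cohort(spec)
        ref = cohort[cohort["group"] == "reference"]
        clin = cohort[cohort["group"] == "clinical"]
        zr = reference_z_scores(ref, model=model, k_folds=k_folds,
                                seed=int(s), restarts=restarts)
        res = fit_normative(ref, model=model, seed=int(s), restarts=restarts)
        zc = res.z_scores(clin)
        tt = welch_ttest(zc, zr)
        hits += tt.p_raw < alpha
    return hits / n_reps
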