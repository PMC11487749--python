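"""Synthetic surfaces and cohorts with known ground truth.

Two generators stand in for data that would normally come from neonatal MRI:

* :func:`generate_bumpy_sphere` builds star-shaped closed meshes whose true
  surface area is available by numerical quadrature of the parametric area
  integral, so the gyrification-index pipeline can be checked against an
  analytic folding level.
* :func:`generate_cohort` draws subject tables with the statistical structure
  the downstream analysis assumes: supratentorial brain volume (STBV) and
  gyrification index (GI) as smooth functions of post-menstrual age (PMA) and
  sex plus Gaussian noise, a clinical group whose GI deficit is either
  volume-mediated (GI follows STBV, and STBV is shifted down) or direct
  (a group term on GI with STBV untouched), and cerebral blood flow linked to
  brain size so that oxygen delivery co-varies with STBV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

log = logging.getLogger(__name__)

__all__ = [
    "SurfaceSpec",
    "LinearGrowth",
    "CBFLink",
    "CohortSpec",
    "generate_bumpy_sphere",
    "generate_cohort",
    "apply_inclusion_filters",
    "REGIONS",
    "COHORT_COLUMNS",
]

# GI column names: whole brain plus the six lobes analysed.
REGIONS = (
    "whole_brain",
    "frontal",
    "occipital",
    "parietal",
    "temporal",
    "cingulate",
    "insula",
)

# Typical regional GI level at PMA 41.5 weeks and residual noise sd.
# Levels follow the ordering seen in term neonates (insula most folded,
# cingulate least); noise sds scale roughly with the level.
_REGION_LEVEL = {
    "whole_brain": (2.96, 0.10),
    "frontal": (2.82, 0.10),
    "occipital": (3.06, 0.11),
    "parietal": (3.27, 0.11),
    "temporal": (2.94, 0.10),
    "cingulate": (2.52, 0.08),
    "insula": (3.70, 0.18),
}

COHORT_COLUMNS = (
    "subject_id",
    "group",
    "subgroup",
    "ga_birth",
    "pma_scan",
    "pna_days",
    "sex",
    "stbv",
    *(f"gi_{r}" for r in REGIONS),
    "sao2",
    "hb_gdl",
    "cbf_lica",
    "cbf_rica",
    "cbf_basilar",
    "cognitive",
    "motor",
    "qchat",
    "imd_rank",
    "age_assessment_months",
    "genetic_dx",
)


@dataclass(frozen=True)
class SurfaceSpec:
    """Parameters of a star-shaped 'bumpy sphere' test surface.

    The radial function is ``r(theta, phi) = R * (1 + a*sin(k*theta)*sin(k*phi))``
    with polar angle theta and azimuth phi; ``a`` is `bump_amplitude`, ``k`` is
    `bump_frequency` and ``R`` is `base_radius` (mm). With ``a = 0`` the mesh
    is a geodesic sphere.
    """

    base_radius: float = 50.0
    bump_amplitude: float = 0.0
    bump_frequency: int = 6
    mesh_subdivisions: int = 4
    seed: int | None = None

    def validate(self) -> None:
        if not self.base_radius > 0:
            raise ValueError("base_radius must be > 0")
        if not (0.0 <= self.bump_amplitude < 0.5):
            raise ValueError(
                "bump_amplitude must lie in [0, 0.5): larger amplitudes risk "
                "self-intersection of the radial surface"
            )
        if self.bump_frequency < 0:
            raise ValueError("bump_frequency must be >= 0")
        if self.mesh_subdivisions < 0:
            raise ValueError("mesh_subdivisions must be >= 0")


def bumpy_sphere_radius(theta, phi, spec: SurfaceSpec):
    """Radial function of the synthetic surface, vectorized (mm)."""
    a, k, R = spec.bump_amplitude, spec.bump_frequency, spec.base_radius
    return R * (1.0 + a * np.sin(k * np.asarray(theta)) * np.sin(k * np.asarray(phi)))


def generate_bumpy_sphere(spec: SurfaceSpec) -> trimesh.Trimesh:
    """Generate a closed star-shaped triangulated surface.

    A geodesic icosphere is radially displaced by the spec's radial function.
    The construction is a pure function of the spec (the seed field is part of
    the spec for API stability; no randomness is used).
    """
    spec.validate()
    base = trimesh.creation.icosphere(subdivisions=spec.mesh_subdivisions, radius=1.0)
    v = np.asarray(base.vertices)
    theta = np.arccos(np.clip(v[:, 2], -1.0, 1.0))
    phi = np.arctan2(v[:, 1], v[:, 0])
    r = bumpy_sphere_radius(theta, phi, spec)
    mesh = trimesh.Trimesh(vertices=v * r[:, None], faces=base.faces, process=False)
    if not mesh.is_watertight:  # pragma: no cover - construction guarantees this
        raise RuntimeError("generated surface is not closed")
    return mesh


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class LinearGrowth:
    """Linear trend ``intercept + slope*(PMA - ref_pma) + sex_effect*sex`` plus
    Gaussian noise with sd `noise_sd`."""

    intercept: float
    slope: float
    sex_effect: float
    noise_sd: float
    ref_pma: float = 41.5

    def mean(self, pma, sex):
        return (
            self.intercept
            + self.slope * (np.asarray(pma) - self.ref_pma)
            + self.sex_effect * np.asarray(sex)
        )


@dataclass(frozen=True)
class CBFLink:
    """Total CBF as a function of STBV: ``cbf_ref + slope*(stbv - stbv_ref)``
    with multiplicative lognormal noise (keeps flows positive)."""

    cbf_ref: float = 85.0  # ml/min at the reference STBV
    stbv_ref: float = 280.0  # cm^3
    slope: float = 0.2  # ml/min per cm^3
    log_noise_sd: float = 0.2
    vessel_alpha: tuple[float, float, float] = (10.0, 10.0, 8.0)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic reference + clinical cohort.

    `deficit_mode` controls how the clinical group differs:

    * ``"none"`` — both groups drawn from the reference process.
    * ``"volume_mediated"`` — clinical STBV shifted down by `stbv_group_gap`
      cm^3 and GI generated as a deterministic function of the STBV residual
      (coupling `gi_stbv_slope` GI units per cm^3) plus noise, with no group
      term on GI itself.
    * ``"direct"`` — a group term of `deficit_size` reference noise sds is
      subtracted from clinical GI; STBV is unchanged.
    """

    n_reference: int = 320
    n_clinical: int = 142
    seed: int = 0
    ga_birth_range: tuple[float, float] = (36.0, 42.0)
    pma_scan_range: tuple[float, float] = (36.0, 46.0)
    stbv_growth: LinearGrowth = field(
        default_factory=lambda: LinearGrowth(320.0, 15.0, 8.0, 25.0, ref_pma=40.0)
    )
    gi_growth: LinearGrowth = field(
        default_factory=lambda: LinearGrowth(2.96, 0.08, 0.0, 0.10, ref_pma=41.5)
    )
    deficit_mode: str = "none"
    deficit_size: float = 0.0
    stbv_group_gap: float = 60.0
    gi_stbv_slope: float = 0.004
    cdo2_link: CBFLink = field(default_factory=CBFLink)
    p_missing_cbf: float = 0.0
    p_missing_outcome: float = 0.0
    subgroup_weights: tuple[float, float, float] = (60.0, 43.0, 39.0)

    def validate(self) -> None:
        if self.n_reference < 0 or self.n_clinical < 0:
            raise ValueError("cohort sizes must be >= 0")
        if self.deficit_mode not in ("none", "volume_mediated", "direct"):
            raise ValueError(f"unknown deficit_mode {self.deficit_mode!r}")
        for g in (self.stbv_growth, self.gi_growth):
            if g.noise_sd < 0:
                raise ValueError("noise sds must be >= 0")
        if not (0 <= self.p_missing_cbf <= 1 and 0 <= self.p_missing_outcome <= 1):
            raise ValueError("missingness rates must lie in [0, 1]")


_SUBGROUPS = ("abnormal_streaming", "left_sided", "right_sided")


def _truncnorm(rng, loc, scale, lo, hi, size):
    """Rejection-sampled truncated normal (cheap at these widths)."""
    out = rng.normal(loc, scale, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(loc, scale, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def _draw_group(rng, spec: CohortSpec, n: int, clinical: bool) -> pd.DataFrame:
    ga_lo, ga_hi = spec.ga_birth_range
    # Under an actual deficit the clinical group is born and scanned earlier
    # (as in real cardiac cohorts); under the null ("none") both groups are
    # exchangeable draws from the reference process, so the demographics match.
    if clinical and spec.deficit_mode != "none":
        ga = _truncnorm(rng, 38.4, 0.8, max(ga_lo, 36.0), min(ga_hi, 41.0), n)
        pna = np.maximum(1, rng.poisson(4.0, n))
    else:
        ga = _truncnorm(rng, 40.3, 1.0, max(ga_lo, 37.0), ga_hi, n)
        pna = np.maximum(1, rng.poisson(7.0, n))
    pma = ga + pna / 7.0
    sex = rng.integers(0, 2, n)

    stbv_mu = spec.stbv_growth.mean(pma, sex)
    stbv_shift = 0.0
    if clinical and spec.deficit_mode == "volume_mediated":
        stbv_shift = -spec.stbv_group_gap
    stbv = stbv_mu + stbv_shift + rng.normal(0.0, spec.stbv_growth.noise_sd, n)
    stbv_resid = stbv - stbv_mu  # residual about the *reference* trend

    wb_level, wb_sd = _REGION_LEVEL["whole_brain"]
    g = spec.gi_growth
    gi_cols = {}
    for region in REGIONS:
        level, sd0 = _REGION_LEVEL[region]
        scale = level / wb_level
        sd = sd0 * (g.noise_sd / wb_sd)
        mu = (
            g.intercept * scale
            + g.slope * scale * (pma - g.ref_pma)
            + g.sex_effect * scale * sex
        )
        gi = mu + rng.normal(0.0, sd, n)
        if spec.deficit_mode == "volume_mediated":
            gi = gi + spec.gi_stbv_slope * scale * stbv_resid
        elif spec.deficit_mode == "direct" and clinical:
            gi = gi - spec.deficit_size * sd
        gi_cols[f"gi_{region}"] = gi

    link = spec.cdo2_link
    cbf_mu = np.maximum(5.0, link.cbf_ref + link.slope * (stbv - link.stbv_ref))
    cbf_total = cbf_mu * np.exp(rng.normal(0.0, link.log_noise_sd, n))
    frac = rng.dirichlet(link.vessel_alpha, size=n)
    flows = frac * cbf_total[:, None]

    if clinical:
        sao2 = _truncnorm(rng, 0.92, 0.05, 0.70, 1.00, n)
    else:
        sao2 = _truncnorm(rng, 0.97, 0.015, 0.90, 1.00, n)
    hb = _truncnorm(rng, 16.7, 2.4, 6.0, 28.0, n)

    if clinical:
        cognitive = rng.normal(93.0, 12.0, n)
        motor = rng.normal(94.0, 12.0, n)
        qchat = rng.normal(29.0, 8.0, n)
        subgroup = rng.choice(
            _SUBGROUPS, size=n, p=np.asarray(spec.subgroup_weights) / sum(spec.subgroup_weights)
        )
        genetic = (rng.random(n) < 0.05).astype(int)
    else:
        cognitive = rng.normal(100.0, 12.0, n)
        motor = rng.normal(100.0, 12.0, n)
        qchat = rng.normal(26.0, 7.0, n)
        subgroup = np.full(n, "none", dtype=object)
        genetic = np.zeros(n, dtype=int)

    df = pd.DataFrame(
        {
            "group": "clinical" if clinical else "reference",
            "subgroup": subgroup,
            "ga_birth": ga,
            "pma_scan": pma,
            "pna_days": pna.astype(float),
            "sex": sex,
            "stbv": stbv,
            **gi_cols,
            "sao2": sao2,
            "hb_gdl": hb,
            "cbf_lica": flows[:, 0],
            "cbf_rica": flows[:, 1],
            "cbf_basilar": flows[:, 2],
            "cognitive": cognitive,
            "motor": motor,
            "qchat": qchat,
            "imd_rank": rng.integers(1, 32845, n),
            "age_assessment_months": rng.normal(22.3, 0.8, n),
            "genetic_dx": genetic,
        }
    )
    if spec.p_missing_cbf > 0:
        miss = rng.random(n) < spec.p_missing_cbf
        df.loc[miss, ["cbf_lica", "cbf_rica", "cbf_basilar"]] = np.nan
    if spec.p_missing_outcome > 0:
        miss = rng.random(n) < spec.p_missing_outcome
        df.loc[miss, ["cognitive", "motor", "qchat"]] = np.nan
    return df


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table, one row per subject, deterministic given the spec.

    Post-natal age (days) satisfies ``pna_days = 7 * (pma_scan - ga_birth)``
    exactly, as PMA is derived from GA plus the sampled post-natal age.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    parts = []
    ref = _draw_group(rng, spec, spec.n_reference, clinical=False)
    ref.insert(0, "subject_id", [f"REF{i:04d}" for i in range(spec.n_reference)])
    parts.append(ref)
    clin = _draw_group(rng, spec, spec.n_clinical, clinical=True)
    clin.insert(0, "subject_id", [f"CHD{i:04d}" for i in range(spec.n_clinical)])
    parts.append(clin)
    out = pd.concat(parts, ignore_index=True)[list(COHORT_COLUMNS)]
    num = out.select_dtypes(include=[np.number])
    if spec.p_missing_cbf == 0 and spec.p_missing_outcome == 0:
        assert np.isfinite(num.to_numpy(dtype=float)).all()
    return out


def apply_inclusion_filters(
    table: pd.DataFrame, pma_window: tuple[float, float], ga_min: float = 0.0
) -> pd.DataFrame:
    """Keep rows with PMA inside the closed window and GA >= ga_min.

    The window is closed on both ends (a scan at exactly the boundary week is
    retained). Row order is preserved; the index is reset.
    """
    lo, hi = pma_window
    if lo > hi:
        raise ValueError("pma_window lower bound exceeds upper bound")
    if len(table) == 0:
        return table.copy()
    for col in ("pma_scan", "ga_birth"):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")
        bad = table.index[table[col].isna()]
        if len(bad):
            raise ValueError(f"row {bad[0]} has missing {col}")
    keep = (table["pma_scan"] >= lo) & (table["pma_scan"] <= hi) & (
        table["ga_birth"] >= ga_min
    )
    return table.loc[keep].reset_index(drop=True)
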