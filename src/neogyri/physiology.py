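"""Total cerebral blood flow and cerebral oxygen delivery (CDO2).

CDO2 is computed with the literal clinical formula

    CDO2 (ml O2/min) = SaO2 * [Hb] (g/dl) * 1.36 * CBF (ml/min)

where 1.36 ml O2 per g Hb is Hüfner's constant and total CBF is the sum of
the flows in the left and right internal carotid and basilar arteries.

Note on units: with Hb on the g/dl scale (e.g. 16.7) this literal product is
the value conventionally reported in the neonatal literature (cohort means
around 1700 ml O2/min). A dimensionally strict evaluation would convert Hb to
g/ml and divide the result by 100; :func:`cdo2_unit_audit` reports both so the
scale convention is explicit rather than silently converted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

HUFNER_CONSTANT = 1.36  # ml O2 bound per gram of haemoglobin

__all__ = ["HUFNER_CONSTANT", "total_cbf", "compute_cdo2", "cdo2_unit_audit", "add_cdo2_column"]


def total_cbf(flows) -> float:
    """Sum of the three vessel flows (ml/min): left ICA, right ICA, basilar."""
    flows = np.asarray(flows, dtype=float)
    if flows.shape != (3,):
        raise ValueError("expected exactly three vessel flows (LICA, RICA, basilar)")
    if not np.isfinite(flows).all():
        raise ValueError("vessel flows must be finite")
    if (flows < 0).any():
        raise ValueError("vessel flows must be non-negative")
    out = float(flows.sum())
    if out == 0.0:
        log.warning("total CBF is 0 ml/min: physiologically implausible")
    return out


def compute_cdo2(
    sao2: float,
    hb_gdl: float,
    cbf_total: float,
    hufner: float = HUFNER_CONSTANT,
    sao2_percent: bool = False,
) -> float:
    """Literal CDO2 product on the conventionally printed scale.

    `sao2` is a fraction of 1; pass ``sao2_percent=True`` to accept a
    percentage (divided by 100). `hb_gdl` is haemoglobin on the g/dl scale.
    """
    if sao2_percent:
        sao2 = sao2 / 100.0
    if not 0.0 < sao2 <= 1.0:
        raise ValueError(
            "sao2 must lie in (0, 1]; pass sao2_percent=True for percentage input"
        )
    if not hb_gdl > 0:
        raise ValueError("hb_gdl must be > 0")
    if not cbf_total > 0:
        raise ValueError("cbf_total must be > 0")
    return sao2 * hb_gdl * hufner * cbf_total


def cdo2_unit_audit(sao2: float, hb_gdl: float, cbf_total: float) -> dict:
    """Report both the literal-formula value and the SI-consistent value.

    The SI-consistent value converts Hb from g/dl to g/ml (factor 1/100), so
    it is exactly the literal value divided by 100.
    """
    literal = compute_cdo2(sao2, hb_gdl, cbf_total)
    return {"literal_gdl_scale": literal, "si_consistent": literal / 100.0}


def add_cdo2_column(table: pd.DataFrame, sao2_percent: bool = False) -> pd.DataFrame:
    """Return a copy of a cohort table with `cbf_total` and `cdo2` columns.

    Rows with any missing input stay missing (complete-case downstream).
    Expects columns sao2, hb_gdl, cbf_lica, cbf_rica, cbf_basilar.
    """
    needed = ["sao2", "hb_gdl", "cbf_lica", "cbf_rica", "cbf_basilar"]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks columns {missing}")
    out = table.copy()
    sao2 = out["sao2"].to_numpy(dtype=float)
    if sao2_percent:
        sao2 = sao2 / 100.0
    with np.errstate(invalid="ignore"):
        if np.nanmax(sao2, initial=0.0) > 1.0:
            raise ValueError("sao2 values above 1; pass sao2_percent=True")
    cbf = out[["cbf_lica", "cbf_rica", "cbf_basilar"]].to_numpy(dtype=float)
    if np.nanmin(cbf, initial=0.0) < 0:
        raise ValueError("negative vessel flow")
    out["cbf_total"] = cbf.sum(axis=1)  # NaN-propagating by design
    out["cdo2"] = sao2 * out["hb_gdl"].to_numpy(dtype=float) * HUFNER_CONSTANT * out["cbf_total"]
    return out
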