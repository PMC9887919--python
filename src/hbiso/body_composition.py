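"""Sarcopenic-obesity (SO) classification from within-cohort quintiles.

SO is defined as skeletal muscle mass (SMM) in the two lowest cohort
quintiles AND fat mass (FM) in the two highest quintiles AND
BMI >= 30 kg/m^2.  "Two lowest quintiles" is operationalised as
SMM <= 40th-percentile cutpoint and "two highest" as FM >= 60th-
percentile cutpoint, both inclusive so that tied or degenerate data
still classify.  Cutpoints are computed on the analysed (post
energy-filter) sample by default; external cutpoints may be supplied
for reference-population use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SOStatus", "quantile", "classify_so", "so_prevalence"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SOStatus:
    """Cutpoints used and per-participant classification flags.

    ``flags`` has boolean columns ``smm_low2``, ``fm_high2``,
    ``bmi_ge30``, ``so`` and ``classifiable``, indexed like the input
    cohort; unclassifiable rows (missing SMM/FM/BMI) carry False flags.
    """

    smm_p40: float
    smm_p60: float
    fm_p40: float
    fm_p60: float
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        if self.smm_p40 > self.smm_p60 or self.fm_p40 > self.fm_p60:
            raise ValueError("quantile cutpoints out of order")


def quantile(values, p: float) -> float:
    """Linear-interpolation sample quantile.

    The k-th order statistic of n values sits at probability
    (k-1)/(n-1); intermediate probabilities interpolate linearly
    (the common statistical-software default).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("cannot take a quantile of an empty sample")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    return float(np.quantile(arr, p, method="linear"))


def classify_so(
    cohort: pd.DataFrame,
    bmi_threshold: float = 30.0,
    external_cutpoints: dict | None = None,
) -> SOStatus:
    """Classify sarcopenic obesity for every participant.

    Parameters
    ----------
    cohort
        Must contain ``smm``, ``fm`` and ``bmi`` columns; needs at
        least 5 rows for quintiles to be meaningful.
    bmi_threshold
        The obesity criterion (kg/m^2); the SO definition keeps
        BMI >= 30 even in cohorts recruited at BMI >= 25.
    external_cutpoints
        Optional ``{"smm_p40": .., "smm_p60": .., "fm_p40": .., "fm_p60": ..}``
        from a reference population; by default cutpoints come from the
        analysed sample itself.
    """
    for col in ("smm", "fm", "bmi"):
        if col not in cohort.columns:
            raise KeyError(f"cohort is missing required column {col!r}")
    if len(cohort) < 5:
        raise ValueError("need at least 5 participants for quintile cutpoints")

    smm = pd.to_numeric(cohort["smm"], errors="coerce")
    fm = pd.to_numeric(cohort["fm"], errors="coerce")
    bmi = pd.to_numeric(cohort["bmi"], errors="coerce")
    classifiable = smm.notna() & fm.notna() & bmi.notna()
    n_bad = int((~classifiable).sum())
    if n_bad:
        log.warning("%d participant(s) unclassifiable due to missing SMM/FM/BMI", n_bad)

    if external_cutpoints is not None:
        cut = external_cutpoints
        smm_p40, smm_p60 = cut["smm_p40"], cut["smm_p60"]
        fm_p40, fm_p60 = cut["fm_p40"], cut["fm_p60"]
    else:
        smm_ok = smm[classifiable]
        fm_ok = fm[classifiable]
        smm_p40, smm_p60 = quantile(smm_ok, 0.40), quantile(smm_ok, 0.60)
        fm_p40, fm_p60 = quantile(fm_ok, 0.40), quantile(fm_ok, 0.60)

    smm_low2 = (smm <= smm_p40) & classifiable
    fm_high2 = (fm >= fm_p60) & classifiable
    bmi_ge30 = (bmi >= bmi_threshold) & classifiable
    so = smm_low2 & fm_high2 & bmi_ge30

    flags = pd.DataFrame(
        {
            "smm_low2": smm_low2,
            "fm_high2": fm_high2,
            "bmi_ge30": bmi_ge30,
            "so": so,
            "classifiable": classifiable,
        },
        index=cohort.index,
    )
    return SOStatus(
        smm_p40=float(smm_p40), smm_p60=float(smm_p60),
        fm_p40=float(fm_p40), fm_p60=float(fm_p60), flags=flags,
    )


def so_prevalence(status: SOStatus) -> float:
    """SO prevalence in percent among classifiable participants."""
    n_class = int(status.flags["classifiable"].sum())
    if n_class == 0:
        raise ValueError("no classifiable participants")
    return 100.0 * float(status.flags["so"].sum()) / n_class
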