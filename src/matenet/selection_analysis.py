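"""Bateman gradients and their sperm-competition decomposition.

The univariate Bateman gradient is the least-squares slope of male
reproductive success T on mating success M.  Adding sperm competition
intensity (SCI) as a second predictor splits it:

    beta_M = beta_{M.SCI} + scic_slope * beta_{SCI.M}

where beta_{M.SCI} and beta_{SCI.M} are the two-predictor partial slopes
and scic_slope is the simple slope of SCI on M.  With all regressions fit
with intercepts under one common standardisation this is the
omitted-variable identity of least squares, and is checked to 1e-10 here.

A fair-raffle paternity generator supplies T: each female's ova are split
evenly among her mates (or proportionally to copulation counts in weighted
networks), either as deterministic expectations or as one multinomial draw
per female.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .network_core import MatingNetwork

__all__ = [
    "UndefinedAnalysisError",
    "ReproductiveOutcome",
    "BatemanDecomposition",
    "fair_raffle_paternity",
    "bateman_gradient",
    "bateman_decomposition",
]

Standardization = Literal["raw", "mean-relative"]


class UndefinedAnalysisError(ValueError):
    """A regression quantity is undefined for the given input."""

    def __init__(self, reason: str, diagnostic: str | None = None):
        self.reason = reason
        self.diagnostic = diagnostic
        msg = reason if diagnostic is None else f"{reason} ({diagnostic})"
        super().__init__(msg)


@dataclass(frozen=True)
class ReproductiveOutcome:
    """Per-male reproductive success under a fair-raffle paternity model.

    ``male_success`` sums to the total fecundity of mated females exactly,
    in both modes (expectation in deterministic mode, by construction in
    multinomial mode).
    """

    male_success: np.ndarray
    fecundities: np.ndarray
    mode: Literal["deterministic", "multinomial"]
    seed: int | None = None


@dataclass(frozen=True)
class BatemanDecomposition:
    beta_m: float
    beta_m_given_sci: float
    beta_sci_given_m: float
    scic_slope: float
    residuals: np.ndarray
    identity_gap: float
    standardization: Standardization
    beta_sci_given_m_negative: bool

    def to_dict(self) -> dict:
        return {
            "beta_m": self.beta_m,
            "beta_m_given_sci": self.beta_m_given_sci,
            "beta_sci_given_m": self.beta_sci_given_m,
            "scic_slope": self.scic_slope,
            "identity_gap": self.identity_gap,
            "standardization": self.standardization,
            "beta_sci_given_m_negative": self.beta_sci_given_m_negative,
            "residuals": self.residuals.tolist(),
        }


def fair_raffle_paternity(
    net: MatingNetwork,
    fecundities: Sequence[float] | np.ndarray,
    mode: Literal["deterministic", "multinomial"] = "deterministic",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ReproductiveOutcome:
    """Allocate each female's ova among her mates under a fair raffle.

    Male i's raffle probability within female j is ``w_ij / W_j`` where
    ``W_j`` is her total copulation count (for unweighted networks this is
    ``1 / k_j``).  Deterministic mode returns the expectations
    ``T_i = sum_j f_j * w_ij / W_j``; multinomial mode draws each female's
    ``f_j`` ova independently (fecundities must then be integers).

    Fecundity assigned to an unmated female cannot be allocated and is
    ignored with a warning.
    """
    fec = np.asarray(fecundities, dtype=np.float64)
    if fec.shape != (net.n_females,):
        raise ValueError(f"fecundities must have length {net.n_females}")
    if np.any(fec < 0):
        raise ValueError("fecundities must be non-negative")
    w = net.effective_weights().astype(np.float64)
    w_tot = w.sum(axis=0)
    unmated = (w_tot == 0) & (fec > 0)
    if unmated.any():
        warnings.warn(
            f"ignoring fecundity of {int(unmated.sum())} unmated female(s) "
            f"(columns {np.flatnonzero(unmated).tolist()})",
            stacklevel=2,
        )
        fec = np.where(w_tot > 0, fec, 0.0)
    prob = np.divide(w, w_tot, out=np.zeros_like(w), where=w_tot > 0)
    if mode == "deterministic":
        t = prob @ fec
        return ReproductiveOutcome(male_success=t, fecundities=fec, mode=mode, seed=seed)
    if mode != "multinomial":
        raise ValueError(f"mode must be 'deterministic' or 'multinomial', got {mode!r}")
    if not np.all(fec == np.round(fec)):
        raise ValueError("multinomial mode requires integer fecundities")
    if rng is None:
        rng = np.random.default_rng(seed)
    t = np.zeros(net.n_males)
    for j in np.flatnonzero((w_tot > 0) & (fec > 0)):
        t += rng.multinomial(int(fec[j]), prob[:, j])
    return ReproductiveOutcome(male_success=t, fecundities=fec, mode=mode, seed=seed)


def _standardize(v: np.ndarray, standardization: Standardization, name: str) -> np.ndarray:
    if standardization == "raw":
        return v
    if standardization == "mean-relative":
        mean = v.mean()
        if mean == 0:
            raise UndefinedAnalysisError(
                "zero-mean", f"mean-relative standardization needs mean({name}) != 0"
            )
        return v / mean
    raise ValueError(f"unknown standardization {standardization!r}")


def _simple_slope(y: np.ndarray, x: np.ndarray) -> float:
    xc = x - x.mean()
    return float((xc * (y - y.mean())).sum() / (xc * xc).sum())


def bateman_gradient(
    T: Sequence[float] | np.ndarray,
    M: Sequence[float] | np.ndarray,
    standardization: Standardization = "mean-relative",
) -> float:
    """Least-squares slope of reproductive success on mating success.

    Mean-relative standardization (the default) divides both variables by
    their means before fitting, which leaves any exact-proportionality
    slope invariant and makes gradients comparable across populations.
    """
    t = np.asarray(T, dtype=np.float64)
    m = np.asarray(M, dtype=np.float64)
    if t.shape != m.shape or t.ndim != 1 or len(t) < 2:
        raise ValueError("T and M must be 1-D arrays of equal length >= 2")
    if np.ptp(m) == 0:
        raise UndefinedAnalysisError("no-male-degree-variance", "var(M) = 0")
    t = _standardize(t, standardization, "T")
    m = _standardize(m, standardization, "M")
    return _simple_slope(t, m)


def bateman_decomposition(
    T: Sequence[float] | np.ndarray,
    M: Sequence[float] | np.ndarray,
    SCI: Sequence[float] | np.ndarray,
    standardization: Standardization = "mean-relative",
) -> BatemanDecomposition:
    """Two-predictor decomposition of the Bateman gradient.

    Fits ``T ~ M + SCI`` (with intercept) under the chosen standardization,
    plus the simple regressions of T on M and of SCI on M, and verifies the
    slope identity ``beta_M = beta_{M.SCI} + scic_slope * beta_{SCI.M}``.

    Note the identity pairs the partial slopes with the *slope* form of the
    M-SCI association, never the correlation form.

    Raises
    ------
    UndefinedAnalysisError
        When var(M) = 0 or when M and SCI are collinear (the diagnostic
        reports their correlation).
    """
    t = np.asarray(T, dtype=np.float64)
    m = np.asarray(M, dtype=np.float64)
    sci = np.asarray(SCI, dtype=np.float64)
    if not (t.shape == m.shape == sci.shape) or t.ndim != 1:
        raise ValueError("T, M and SCI must be 1-D arrays of equal length")
    if len(t) < 3:
        raise ValueError("decomposition needs at least 3 males")
    if np.ptp(m) == 0:
        raise UndefinedAnalysisError("no-male-degree-variance", "var(M) = 0")
    t = _standardize(t, standardization, "T")
    m = _standardize(m, standardization, "M")
    sci = _standardize(sci, standardization, "SCI")

    sci_constant = np.ptp(sci) == 0
    if not sci_constant:
        r_msci = np.corrcoef(m, sci)[0, 1]
        if abs(r_msci) > 1 - 1e-12:
            raise UndefinedAnalysisError(
                "collinear-predictors", f"corr(M, SCI) = {r_msci:.6f}"
            )

    beta_m = _simple_slope(t, m)
    if sci_constant:
        # SCI carries no information: partials collapse to the simple fit.
        beta_m_given_sci = beta_m
        beta_sci_given_m = 0.0
        scic_slope = 0.0
        residuals = t - t.mean() - beta_m * (m - m.mean())
    else:
        x = np.column_stack((np.ones_like(m), m, sci))
        coef, *_ = np.linalg.lstsq(x, t, rcond=None)
        beta_m_given_sci = float(coef[1])
        beta_sci_given_m = float(coef[2])
        scic_slope = _simple_slope(sci, m)
        residuals = t - x @ coef
    gap = abs(beta_m - (beta_m_given_sci + scic_slope * beta_sci_given_m))
    return BatemanDecomposition(
        beta_m=beta_m,
        beta_m_given_sci=beta_m_given_sci,
        beta_sci_given_m=beta_sci_given_m,
        scic_slope=scic_slope,
        residuals=residuals,
        identity_gap=float(gap),
        standardization=standardization,
        beta_sci_given_m_negative=beta_sci_given_m < 0,
    )
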