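"""Assortativity-by-mating-success metrics for bipartite mating networks.

Three families of statistics are provided, all operating on node degree
(mating success):

* degree assortativity ``r`` — the Pearson correlation between the degrees
  at the two ends of each edge, in a directed variant (each mating pair
  contributes one male->female observation) and an undirected variant
  (each pair contributes both orientations);
* NODF nestedness — percentage overlap under decreasing fill across all
  row pairs and column pairs of the degree-sorted incidence matrix, on a
  0-100 scale;
* sperm competition intensity (SCI) — the harmonic mean of a male's
  partners' mating successes, equal to the reciprocal of his mean
  fair-raffle paternity share — and its population-level association with
  male mating success (SCIC), as either a Pearson correlation or a
  mean-standardised regression slope.

Individuals that did not mate at all are excluded from every metric
computation by default: assortativity of mating partners is a property of
the mated population, and unmated individuals would otherwise leak into
degree variances and the NODF pair count.

Correlation-type metrics return an explicit UNDEFINED state (with a reason
code) whenever a variance precondition fails, rather than NaN, so degenerate
mating systems (monogamy, pure polygyny, ...) are reported faithfully.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .network_core import MatingNetwork, DegreeSummary, degrees, mating_density

__all__ = [
    "UNDEF_NO_MALE_VAR",
    "UNDEF_NO_FEMALE_VAR",
    "UNDEF_NO_EDGE_END_VAR",
    "UNDEF_EMPTY",
    "MetricValue",
    "EdgeTraitPairs",
    "NodfDetail",
    "SCIResult",
    "MetricReport",
    "edge_trait_pairs",
    "newman_assortativity",
    "nodf",
    "sperm_competition_intensity",
    "scic",
    "metric_report",
]

UNDEF_NO_MALE_VAR = "no-male-degree-variance"
UNDEF_NO_FEMALE_VAR = "no-female-degree-variance"
UNDEF_NO_EDGE_END_VAR = "no-edge-end-variance"
UNDEF_EMPTY = "empty-network"

Mode = Literal["directed", "undirected"]


@dataclass(frozen=True)
class MetricValue:
    """A metric result that is either a number or explicitly undefined.

    Exactly one of ``value`` and ``reason`` is set.  ``reason`` is one of
    the ``UNDEF_*`` codes.
    """

    value: float | None = None
    reason: str | None = None

    def __post_init__(self) -> None:
        if (self.value is None) == (self.reason is None):
            raise ValueError("exactly one of value and reason must be set")

    @property
    def is_defined(self) -> bool:
        return self.value is not None

    @classmethod
    def defined(cls, value: float) -> "MetricValue":
        return cls(value=float(value))

    @classmethod
    def undefined(cls, reason: str) -> "MetricValue":
        return cls(reason=reason)

    def as_string(self, fmt: str = "{:.6f}") -> str:
        """Render as a number or ``NA:<reason>``."""
        if self.is_defined:
            return fmt.format(self.value)
        return f"NA:{self.reason}"

    def __float__(self) -> float:
        if self.value is None:
            return float("nan")
        return self.value


@dataclass(frozen=True)
class EdgeTraitPairs:
    """Degree values at the two ends of each edge.

    ``pairs`` has shape (E, 2) for directed mode — one ``(male degree,
    female degree)`` row per mating pair — and shape (2E, 2) for undirected
    mode, where the directed list is concatenated with its coordinate swap
    so that each copulation is viewed from both ends.
    """

    mode: Mode
    pairs: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pairs, dtype=np.int64)
        arr.setflags(write=False)
        object.__setattr__(self, "pairs", arr)


@dataclass(frozen=True)
class NodfDetail:
    """Pairwise NODF breakdown on the degree-sorted mated submatrix.

    ``row_order`` / ``col_order`` give the original (full-network) indices
    of the mated rows/columns after sorting by decreasing degree.  The
    per-pair arrays follow upper-triangle order of the sorted matrix:
    ``row_pairs[p] = (i, j)`` are *positions* in ``row_order`` with i above
    j.  ``value`` is the aggregate NODF in [0, 100].
    """

    row_order: np.ndarray
    col_order: np.ndarray
    row_pairs: np.ndarray
    row_df: np.ndarray
    row_po: np.ndarray
    row_n: np.ndarray
    col_pairs: np.ndarray
    col_df: np.ndarray
    col_po: np.ndarray
    col_n: np.ndarray
    value: float


@dataclass(frozen=True)
class SCIResult:
    """Per-male sperm competition intensity.

    ``sci[i]`` is the harmonic mean mating success of male i's partners
    (>= 1 where defined) and ``paternity_share[i] = 1 / sci[i]`` his mean
    fair-raffle paternity share.  Unmated males get NaN in both arrays.
    In the weighted variant, a male's share within each partner is his
    fraction of her total copulations rather than 1 over her partner count.
    """

    sci: np.ndarray
    paternity_share: np.ndarray
    weighted: bool


@dataclass(frozen=True)
class MetricReport:
    """All assortativity statistics for one network, with UNDEFINED states."""

    r_newman_u: MetricValue
    r_newman_d: MetricValue
    nodf: MetricValue
    scic_corr: MetricValue
    scic_slope: MetricValue
    degree_summary: DegreeSummary
    density: float

    def to_dict(self) -> dict:
        def cell(mv: MetricValue):
            return mv.value if mv.is_defined else f"NA:{mv.reason}"

        return {
            "r_newman_u": cell(self.r_newman_u),
            "r_newman_d": cell(self.r_newman_d),
            "nodf": cell(self.nodf),
            "scic_corr": cell(self.scic_corr),
            "scic_slope": cell(self.scic_slope),
            "density": self.density,
            "male_degrees": self.degree_summary.male_degrees.tolist(),
            "female_degrees": self.degree_summary.female_degrees.tolist(),
            "male_mean_degree": self.degree_summary.male_mean,
            "male_var_degree": self.degree_summary.male_var,
            "female_mean_degree": self.degree_summary.female_mean,
            "female_var_degree": self.degree_summary.female_var,
        }


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _mated_submatrix(net: MatingNetwork) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Incidence restricted to mated individuals, plus original indices."""
    inc = net.incidence
    row_idx = np.flatnonzero(inc.sum(axis=1) > 0)
    col_idx = np.flatnonzero(inc.sum(axis=0) > 0)
    return inc[np.ix_(row_idx, col_idx)], row_idx, col_idx


# ---------------------------------------------------------------------------
# degree assortativity
# ---------------------------------------------------------------------------

def edge_trait_pairs(net: MatingNetwork, mode: Mode = "directed") -> EdgeTraitPairs:
    """Degree pairs at the two ends of every edge.

    Directed mode yields one ``(male degree, female degree)`` pair per
    mating pair; undirected mode appends the coordinate swap of that list,
    doubling the edge count.
    """
    if mode not in ("directed", "undirected"):
        raise ValueError(f"mode must be 'directed' or 'undirected', got {mode!r}")
    if net.n_edges == 0:
        raise ValueError("empty network: no edges")
    deg = degrees(net)
    rows, cols = np.nonzero(net.incidence)
    directed = np.column_stack((deg.male_degrees[rows], deg.female_degrees[cols]))
    if mode == "directed":
        return EdgeTraitPairs(mode=mode, pairs=directed)
    return EdgeTraitPairs(mode=mode, pairs=np.vstack((directed, directed[:, ::-1])))


def newman_assortativity(net: MatingNetwork, mode: Mode = "directed") -> MetricValue:
    """Degree assortativity: Pearson correlation of end degrees over edges.

    Computed in the population-moment form

        r = [sum(jk) - sum(j) sum(k) / E]
            / sqrt{[sum(j^2) - sum(j)^2/E] [sum(k^2) - sum(k)^2/E]}

    over the edge trait pairs; Pearson correlation is scale-invariant so
    any consistent normalisation gives the same ratio.  UNDEFINED with
    reason ``no-edge-end-variance`` when either coordinate is constant
    across pairs.
    """
    pairs = edge_trait_pairs(net, mode).pairs.astype(np.float64)
    j, k = pairs[:, 0], pairs[:, 1]
    e = len(j)
    sj, sk = j.sum(), k.sum()
    num = (j * k).sum() - sj * sk / e
    var_j = (j * j).sum() - sj * sj / e
    var_k = (k * k).sum() - sk * sk / e
    if var_j <= 0 or var_k <= 0:
        return MetricValue.undefined(UNDEF_NO_EDGE_END_VAR)
    return MetricValue.defined(num / np.sqrt(var_j * var_k))


# ---------------------------------------------------------------------------
# NODF nestedness
# ---------------------------------------------------------------------------

def nodf(net: MatingNetwork, include_unmated: bool = False) -> NodfDetail:
    """NODF nestedness of the incidence matrix, on a 0-100 scale.

    Rows and columns are sorted by decreasing degree.  For each ordered
    pair (upper i, lower j) of rows: decreasing fill DF = 100 iff the
    lower degree is strictly smaller (ties give 0); percentage overlap
    PO = 100 x (shared partners) / (lower degree); the pair's nestedness
    N is PO when DF = 100 and 0 otherwise.  Column pairs are treated the
    same way on the transpose.  The aggregate is sum(N) over all pairs
    divided by f(f-1)/2 + m(m-1)/2.

    Because ties yield DF = 0, the result is invariant to the tie-break
    order among equal-degree rows or columns.  A pair member with degree 0
    (only possible with ``include_unmated=True``) gets PO = 0 by
    convention to guard the division.
    """
    if net.n_males < 2 and net.n_females < 2:
        raise ValueError("NODF needs at least two rows or two columns")
    if include_unmated:
        sub = net.incidence
        row_idx = np.arange(net.n_males)
        col_idx = np.arange(net.n_females)
    else:
        sub, row_idx, col_idx = _mated_submatrix(net)

    def axis_pairs(a: np.ndarray):
        """DF/PO/N for all ordered pairs of rows of ``a`` (sorted here)."""
        deg = a.sum(axis=1)
        order = np.argsort(-deg, kind="stable")
        a = a[order]
        deg = deg[order]
        n = a.shape[0]
        if n < 2:
            empty = np.empty(0)
            return order, np.empty((0, 2), dtype=np.int64), empty, empty, empty
        iu, ju = np.triu_indices(n, k=1)
        df = np.where(deg[ju] < deg[iu], 100.0, 0.0)
        shared = (a @ a.T)[iu, ju].astype(np.float64)
        lower = deg[ju].astype(np.float64)
        po = np.where(lower > 0, 100.0 * shared / np.where(lower > 0, lower, 1), 0.0)
        nij = np.where(df == 100.0, po, 0.0)
        return order, np.column_stack((iu, ju)), df, po, nij

    r_ord, r_pairs, r_df, r_po, r_n = axis_pairs(sub)
    c_ord, c_pairs, c_df, c_po, c_n = axis_pairs(sub.T)
    m, f = sub.shape
    denom = f * (f - 1) / 2 + m * (m - 1) / 2
    value = (r_n.sum() + c_n.sum()) / denom if denom > 0 else 0.0
    return NodfDetail(
        row_order=row_idx[r_ord],
        col_order=col_idx[c_ord],
        row_pairs=r_pairs,
        row_df=r_df,
        row_po=r_po,
        row_n=r_n,
        col_pairs=c_pairs,
        col_df=c_df,
        col_po=c_po,
        col_n=c_n,
        value=float(value),
    )


# ---------------------------------------------------------------------------
# sperm competition intensity
# ---------------------------------------------------------------------------

def sperm_competition_intensity(net: MatingNetwork, weighted: bool = False) -> SCIResult:
    """Harmonic-mean sperm competition intensity per male.

    Unweighted: a male's mean paternity share is
    ``s_i = (1/M_i) * sum_j 1/k_j`` over his partners j (k_j = partner's
    mating success) and ``SCI_i = 1/s_i``.  Weighted: his share within
    female j is his fraction ``w_ij / W_j`` of her total copulations, so
    ``s_i = (1/M_i) * sum_j w_ij / W_j``.  Males with degree 0 get NaN.
    """
    inc = net.incidence.astype(np.float64)
    m_deg = inc.sum(axis=1)
    if weighted:
        w = net.effective_weights().astype(np.float64)
        w_tot = w.sum(axis=0)
        per_female = np.divide(w, w_tot, out=np.zeros_like(w), where=w_tot > 0)
    else:
        k = inc.sum(axis=0)
        inv_k = np.divide(1.0, k, out=np.zeros_like(k), where=k > 0)
        per_female = inc * inv_k
    with np.errstate(invalid="ignore", divide="ignore"):
        share = per_female.sum(axis=1) / m_deg
    share = np.where(m_deg > 0, share, np.nan)
    with np.errstate(invalid="ignore"):
        sci = 1.0 / share
    return SCIResult(sci=sci, paternity_share=share, weighted=weighted)


def scic(
    net: MatingNetwork,
    form: Literal["correlation", "slope"] = "correlation",
    weighted: bool = False,
) -> MetricValue:
    """Association between male mating success and his SCI across males.

    ``correlation`` form: Pearson correlation of (M_i, SCI_i) over mated
    males.  ``slope`` form: least-squares slope of SCI_i / mean(SCI) on
    M_i / mean(M) (both variables standardised by their means).  Positive
    values mean the most successful males face the most intense sperm
    competition.

    UNDEFINED with ``no-male-degree-variance`` when all mated males have
    the same degree; the correlation form is additionally UNDEFINED
    (``no-female-degree-variance``) when SCI is constant across males.
    """
    if form not in ("correlation", "slope"):
        raise ValueError(f"form must be 'correlation' or 'slope', got {form!r}")
    m_deg = net.incidence.sum(axis=1)
    mated = m_deg > 0
    if mated.sum() < 2:
        raise ValueError("SCIC needs at least 2 mated males")
    m = m_deg[mated].astype(np.float64)
    sci = sperm_competition_intensity(net, weighted=weighted).sci[mated]
    if np.ptp(m) == 0:
        return MetricValue.undefined(UNDEF_NO_MALE_VAR)
    if form == "correlation":
        if np.ptp(sci) == 0:
            return MetricValue.undefined(UNDEF_NO_FEMALE_VAR)
        mc = m - m.mean()
        sc = sci - sci.mean()
        return MetricValue.defined(
            (mc * sc).sum() / np.sqrt((mc * mc).sum() * (sc * sc).sum())
        )
    x = m / m.mean()
    y = sci / sci.mean()
    xc = x - x.mean()
    return MetricValue.defined(float((xc * (y - y.mean())).sum() / (xc * xc).sum()))


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def metric_report(net: MatingNetwork) -> MetricReport:
    """All four assortativity statistics (plus the SCIC slope form).

    Degree-zero individuals are excluded from metric computations; the
    degree summary and density describe the full network as given.
    """
    deg = degrees(net)
    dens = mating_density(net)
    if net.n_edges == 0:
        empty = MetricValue.undefined(UNDEF_EMPTY)
        return MetricReport(
            r_newman_u=empty,
            r_newman_d=empty,
            nodf=MetricValue.defined(0.0),
            scic_corr=empty,
            scic_slope=empty,
            degree_summary=deg,
            density=dens,
        )
    sub, _, _ = _mated_submatrix(net)
    if sub.shape[0] >= 2 or sub.shape[1] >= 2:
        nodf_mv = MetricValue.defined(nodf(net).value)
    else:
        nodf_mv = MetricValue.defined(0.0)  # single mated pair: no pairs to nest
    mated_males = int((net.incidence.sum(axis=1) > 0).sum())
    if mated_males >= 2:
        scic_corr = scic(net, form="correlation")
        scic_slope = scic(net, form="slope")
    else:
        scic_corr = MetricValue.undefined(UNDEF_NO_MALE_VAR)
        scic_slope = MetricValue.undefined(UNDEF_NO_MALE_VAR)
    return MetricReport(
        r_newman_u=newman_assortativity(net, "undirected"),
        r_newman_d=newman_assortativity(net, "directed"),
        nodf=nodf_mv,
        scic_corr=scic_corr,
        scic_slope=scic_slope,
        degree_summary=deg,
        density=dens,
    )
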