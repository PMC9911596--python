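"""Confocal smFRET burst analysis with PIE filtering and γ/LK/Di correction.

The pipeline mirrors the bin-then-threshold procedure used for diffusing
single molecules under pulsed interleaved excitation (PIE): photon streams
are binned (1 ms default), maximal runs of bins above a count threshold are
collected as bursts, bursts below a minimum photon count are discarded, and
donor-only / acceptor-only molecules are excluded using the
acceptor-excitation channel.  Per-burst FRET efficiency is corrected for
donor leakage (LK), acceptor direct excitation (Di) and the detection factor
γ::

    F_corr = F_DA - LK * F_DD - Di * F_AA
    E      = F_corr / (F_corr + gamma * F_DD)

with the calibrated constants LK = 0.13, Di = 0.06, γ = 0.47 as defaults.
LK and Di enter as multiplicative fractions of the donor-channel and
acceptor-excitation counts (the standard ALEX/PIE calibration convention);
with neutral parameters (LK = Di = 0, γ = 1) E reduces to the proximity
ratio F_DA / (F_DA + F_DD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "CorrectionParams",
    "BurstSearchParams",
    "BinnedTrace",
    "Burst",
    "BurstLabel",
    "FretHistogram",
    "PopulationSummary",
    "bin_stream",
    "find_bursts",
    "classify_burst_pie",
    "corrected_efficiency",
    "stoichiometry",
    "process_stream",
    "build_histogram",
    "summarize_populations",
    "bursts_to_frame",
    "write_burst_table",
    "read_burst_table",
]


@dataclass(frozen=True)
class CorrectionParams:
    """Calibrated instrument and fluorophore constants.

    LK — donor spectral leakage into the acceptor channel, as a fraction of
    F_DD; Di — acceptor direct excitation by the donor laser, as a fraction
    of F_AA; gamma — detection-efficiency/quantum-yield factor; r0 — Förster
    radius of the dye pair in Å.
    """

    lk: float = 0.13
    di: float = 0.06
    gamma: float = 0.47
    r0: float = 52.0

    def __post_init__(self) -> None:
        if self.lk < 0 or self.di < 0:
            raise ValueError("LK and Di must be non-negative")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if not self.r0 > 0:
            raise ValueError("R0 must be positive")

    @classmethod
    def neutral(cls) -> "CorrectionParams":
        """Parameters under which E is the uncorrected proximity ratio."""
        return cls(lk=0.0, di=0.0, gamma=1.0)


@dataclass(frozen=True)
class BurstSearchParams:
    """Binning and burst-search settings.

    bin_width is in ms; threshold is the per-bin total count (DD+DA+AA) a bin
    must reach to seed/extend a burst (admissible range in routine use 6–12);
    min_photons is the minimum summed count for a run of bins to be retained
    as a burst.
    """

    bin_width_ms: float = 1.0
    threshold: int = 8
    min_photons: int = 35
    min_aa: int = 5
    min_dd: int = 5

    def __post_init__(self) -> None:
        if not self.bin_width_ms > 0:
            raise ValueError("bin_width_ms must be positive")
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")
        if self.min_photons < 1:
            raise ValueError("min_photons must be >= 1")


@dataclass
class BinnedTrace:
    """Per-bin photon counts for the three PIE streams."""

    bin_width_ms: float
    dd: np.ndarray
    da: np.ndarray
    aa: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.dd + self.da + self.aa

    @property
    def n_bins(self) -> int:
        return len(self.dd)


class BurstLabel(str, Enum):
    FRET = "fret"
    DONOR_ONLY = "donor_only"
    ACCEPTOR_ONLY = "acceptor_only"


@dataclass
class Burst:
    """One detected single-molecule transit.

    start_bin/end_bin are inclusive 0-based bin indices; F_DD, F_DA, F_AA are
    the summed photon counts of the three PIE streams over those bins; E and
    S are filled by the correction step, label by PIE classification.
    """

    start_bin: int
    end_bin: int
    f_dd: int
    f_da: int
    f_aa: int
    e: float | None = None
    s: float | None = None
    label: BurstLabel | None = None

    @property
    def total(self) -> int:
        return self.f_dd + self.f_da + self.f_aa


@dataclass
class FretHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    n_bursts: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mode(self) -> float:
        """Center of the most populated E bin."""
        if self.n_bursts == 0:
            raise ValueError("empty histogram has no mode")
        return float(self.bin_centers[int(np.argmax(self.counts))])


@dataclass
class PopulationSummary:
    """Gaussian-mixture description of a corrected-E sample."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    kde_mode: float
    n_values: int


# ---------------------------------------------------------------------------
# binning and burst search

def bin_stream(stream, params: BurstSearchParams = BurstSearchParams()) -> BinnedTrace:
    """Bin a photon stream into per-ms DD/DA/AA count traces.

    Bin k covers the half-open interval [k*w, (k+1)*w).  Events in the
    (donor emission, acceptor excitation) slot carry no FRET information and
    are discarded; all other events are conserved into exactly one stream.
    """
    from .photon_sim import Channel, Excitation  # local import avoids cycle

    w_ns = params.bin_width_ms * 1e6
    ts = stream.timestamps_ns
    if len(ts) == 0:
        z = np.zeros(0, dtype=np.int64)
        return BinnedTrace(params.bin_width_ms, z, z.copy(), z.copy())
    n_bins = int(ts[-1] // w_ns) + 1
    idx = (ts // w_ns).astype(np.int64)
    don_em = stream.channels == Channel.DONOR_EM.value
    don_ex = stream.excitations == Excitation.DONOR_EX.value
    masks = {
        "dd": don_em & don_ex,
        "da": ~don_em & don_ex,
        "aa": ~don_em & ~don_ex,
    }
    traces = {
        k: np.bincount(idx[m], minlength=n_bins).astype(np.int64)
        for k, m in masks.items()
    }
    return BinnedTrace(params.bin_width_ms, traces["dd"], traces["da"], traces["aa"])


def find_bursts(trace: BinnedTrace, params: BurstSearchParams = BurstSearchParams()) -> list[Burst]:
    """Locate bursts as maximal runs of bins with total count >= threshold.

    Runs whose summed total falls below ``min_photons`` are discarded.
    Returned bursts are disjoint, ordered, and carry summed F_DD/F_DA/F_AA;
    E, S and label are left unset.
    """
    total = trace.total
    above = total >= params.threshold
    if not above.any():
        return []
    # run boundaries from the sign changes of the boolean mask
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(above) - 1]
    bursts = []
    for s, e in zip(starts, ends):
        sl = slice(s, e + 1)
        f_dd = int(trace.dd[sl].sum())
        f_da = int(trace.da[sl].sum())
        f_aa = int(trace.aa[sl].sum())
        if f_dd + f_da + f_aa >= params.min_photons:
            bursts.append(Burst(int(s), int(e), f_dd, f_da, f_aa))
    return bursts


def classify_burst_pie(burst: Burst, min_aa: int = 5, min_dd: int = 5) -> BurstLabel:
    """PIE species filter.

    A burst without acceptor-excitation signal (F_AA < min_aa) comes from a
    donor-only molecule; one without donor-excitation donor emission
    (F_DD < min_dd) from an acceptor-only molecule; the rest are genuine
    donor+acceptor (FRET) species.
    """
    if burst.f_aa < min_aa:
        return BurstLabel.DONOR_ONLY
    if burst.f_dd < min_dd:
        return BurstLabel.ACCEPTOR_ONLY
    return BurstLabel.FRET


# ---------------------------------------------------------------------------
# correction

def corrected_efficiency(f_dd, f_da, f_aa, params: CorrectionParams) -> float:
    """Corrected per-burst FRET efficiency.

    May fall outside [0, 1] for noisy bursts; never clamped.  Raises when the
    donor-excitation counts are both zero (efficiency undefined).
    """
    if f_dd + f_da <= 0:
        raise ValueError("efficiency undefined: no donor-excitation photons")
    f_corr = f_da - params.lk * f_dd - params.di * f_aa
    return float(f_corr / (f_corr + params.gamma * f_dd))


def stoichiometry(f_dd, f_da, f_aa, params: CorrectionParams) -> float:
    """ALEX stoichiometry S = (γ·F_DD + F_corr) / (γ·F_DD + F_corr + F_AA).

    S near 1 flags donor-only and S near 0 acceptor-only molecules,
    complementing the count-threshold PIE filter.
    """
    f_corr = f_da - params.lk * f_dd - params.di * f_aa
    num = params.gamma * f_dd + f_corr
    denom = num + f_aa
    if denom == 0:
        raise ValueError("stoichiometry undefined: all-zero counts")
    return float(num / denom)


def process_stream(
    stream,
    search: BurstSearchParams = BurstSearchParams(),
    correction: CorrectionParams = CorrectionParams(),
) -> list[Burst]:
    """Full burst pipeline: bin, search, PIE-classify, correct.

    E and S are computed for every burst with donor-excitation photons;
    downstream histogramming uses only label == fret bursts.
    """
    trace = bin_stream(stream, search)
    bursts = find_bursts(trace, search)
    for b in bursts:
        b.label = classify_burst_pie(b, search.min_aa, search.min_dd)
        if b.f_dd + b.f_da > 0:
            b.e = corrected_efficiency(b.f_dd, b.f_da, b.f_aa, correction)
            b.s = stoichiometry(b.f_dd, b.f_da, b.f_aa, correction)
    return bursts


# ---------------------------------------------------------------------------
# histogram and populations

def build_histogram(
    bursts: list[Burst],
    e_bin_width: float = 0.025,
    e_range: tuple[float, float] = (-0.1, 1.1),
) -> FretHistogram:
    """Histogram of corrected E over FRET-labelled bursts.

    The default range [-0.1, 1.1] accommodates shot-noise excursions outside
    [0, 1]; out-of-range values are clipped into the edge bins so the counts
    always sum to the number of contributing bursts.
    """
    lo, hi = e_range
    n_bins = int(round((hi - lo) / e_bin_width))
    edges = lo + e_bin_width * np.arange(n_bins + 1)
    e_vals = np.array(
        [b.e for b in bursts if b.label == BurstLabel.FRET and b.e is not None]
    )
    if len(e_vals) == 0:
        return FretHistogram(edges, np.zeros(n_bins, dtype=int), 0)
    clipped = np.clip(e_vals, lo, np.nextafter(hi, lo))
    counts, _ = np.histogram(clipped, bins=edges)
    return FretHistogram(edges, counts, len(e_vals))


def _em_gmm_1d(x: np.ndarray, means: np.ndarray, sds: np.ndarray, weights: np.ndarray,
               n_iter: int = 500, tol: float = 1e-10):
    """Expectation-maximization for a 1-D Gaussian mixture (fixed k)."""
    n = len(x)
    ll_old = -np.inf
    min_sd = 1e-4
    for _ in range(n_iter):
        # E step: responsibilities
        log_p = (
            -0.5 * ((x[:, None] - means) / sds) ** 2
            - np.log(sds)
            - 0.5 * np.log(2 * np.pi)
            + np.log(weights)
        )
        m = log_p.max(axis=1, keepdims=True)
        p = np.exp(log_p - m)
        norm = p.sum(axis=1, keepdims=True)
        ll = float(np.sum(m.ravel() + np.log(norm.ravel())))
        r = p / norm
        # M step
        nk = r.sum(axis=0)
        weights = nk / n
        means = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - means) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, min_sd**2))
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return means, sds, weights, ll


def summarize_populations(
    e_values,
    n_components: int = 2,
    seed: int = 0,
) -> PopulationSummary:
    """Fit an n-component Gaussian mixture to corrected-E values by EM.

    Initialization is a seeded k-means-style split (quantile centers with a
    small seeded jitter, then one assignment pass); components are reported
    ordered by mean.  The kernel-smoothed mode of the raw sample is reported
    alongside the fit.  Deterministic for a given seed.
    """
    x = np.asarray(e_values, dtype=float)
    if len(x) < 20:
        raise ValueError(f"need at least 20 E values, got {len(x)}")
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")

    spread = float(x.std())
    if spread < 1e-12:
        # degenerate sample: single point mass
        means = np.full(n_components, x.mean())
        return PopulationSummary(
            means=means,
            sds=np.zeros(n_components),
            weights=np.full(n_components, 1.0 / n_components),
            log_likelihood=np.inf,
            kde_mode=float(x.mean()),
            n_values=len(x),
        )

    rng = np.random.default_rng(seed)
    qs = np.linspace(0, 1, n_components + 2)[1:-1]
    means = np.quantile(x, qs) + rng.normal(0, 0.01 * spread, n_components)
    # one k-means assignment pass to seed means/sds/weights
    assign = np.argmin(np.abs(x[:, None] - means), axis=1)
    sds = np.empty(n_components)
    weights = np.empty(n_components)
    for k in range(n_components):
        sel = x[assign == k]
        if len(sel) == 0:
            sel = x
        means[k] = sel.mean()
        sds[k] = max(sel.std(), 0.05 * spread, 1e-3)
        weights[k] = max(len(sel), 1) / len(x)
    weights /= weights.sum()

    means, sds, weights, ll = _em_gmm_1d(x, means, sds, weights)
    order = np.argsort(means)

    kde = gaussian_kde(x)
    grid = np.linspace(x.min() - 3 * spread, x.max() + 3 * spread, 2048)
    kde_mode = float(grid[int(np.argmax(kde(grid)))])

    return PopulationSummary(
        means=means[order],
        sds=sds[order],
        weights=weights[order],
        log_likelihood=ll,
        kde_mode=kde_mode,
        n_values=len(x),
    )


# ---------------------------------------------------------------------------
# tabular IO

_BURST_COLUMNS = [
    "burst_id", "start_ms", "end_ms", "F_DD", "F_DA", "F_AA", "E", "S", "label",
]


def bursts_to_frame(bursts: list[Burst], bin_width_ms: float = 1.0) -> pd.DataFrame:
    rows = [
        {
            "burst_id": i,
            "start_ms": b.start_bin * bin_width_ms,
            "end_ms": (b.end_bin + 1) * bin_width_ms,
            "F_DD": b.f_dd,
            "F_DA": b.f_da,
            "F_AA": b.f_aa,
            "E": np.nan if b.e is None else b.e,
            "S": np.nan if b.s is None else b.s,
            "label": "" if b.label is None else b.label.value,
        }
        for i, b in enumerate(bursts)
    ]
    return pd.DataFrame(rows, columns=_BURST_COLUMNS)


def write_burst_table(bursts: list[Burst], path, bin_width_ms: float = 1.0) -> None:
    bursts_to_frame(bursts, bin_width_ms).to_csv(path, sep="\t", index=False)


def read_burst_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_BURST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"burst table missing columns: {sorted(missing)}")
    return df
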