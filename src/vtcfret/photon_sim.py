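"""Synthetic PIE confocal photon streams with known ground truth.

Simulates the raw observable of a diffusion-based smFRET experiment: single
molecules transiting the confocal volume emit photon bursts recorded in
three streams — donor excitation/donor emission (DD), donor excitation/
acceptor emission (DA) and acceptor excitation/acceptor emission (AA) —
on top of Poisson background.  The generator is the exact algebraic inverse
of the per-burst correction formula in :mod:`vtcfret.burst`: for a species
with true efficiency ``E`` and correction constants (LK, Di, γ), each
transit draws a donor-excitation photon budget ``B`` (log-normal) and an
acceptor-excitation count ``F_AA`` (Poisson), then partitions ``B`` between
the DD and DA channels so the *expected* counts satisfy::

    F_DD = c (1 - E)
    F_DA = c (γ E + LK (1 - E)) + Di F_AA
    with  c = (B - Di F_AA) / ((1 - E)(1 + LK) + γ E)

so that applying the correction to the expectations returns ``E`` exactly,
and F_DD + F_DA = B photon-for-photon in every transit.  Diffusion is not
modelled: a transit is a rectangular burst spread uniformly over an
exponential dwell (default mean 1.5 ms), which is sufficient for the
binning and threshold logic downstream.  All randomness flows from one
integer seed through a single generator, making streams byte-identical
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .burst import CorrectionParams

__all__ = [
    "Channel",
    "Excitation",
    "SpeciesSpec",
    "SimConfig",
    "PhotonStream",
    "simulate_stream",
    "expected_counts",
    "write_photon_table",
    "read_photon_table",
    "read_sim_config",
]


class Channel(Enum):
    DONOR_EM = 0
    ACCEPTOR_EM = 1


class Excitation(Enum):
    DONOR_EX = 0
    ACCEPTOR_EX = 1


@dataclass(frozen=True)
class SpeciesSpec:
    """One FRET species in the simulated mixture.

    ``true_e`` is the ground-truth transfer efficiency (alternatively supply
    ``true_r`` in Å together with the Förster radius of the correction
    parameters and convert via :func:`vtcfret.forster.efficiency_from_distance`).
    ``fraction`` is the molar fraction of transits drawn from this species;
    fractions over all species must sum to 1.  The donor-excitation photon
    budget per transit is log-normal with mean ``mean_burst_size`` and
    log-scale spread ``burst_size_shape`` (burst-size distributions of
    diffusing molecules are heavy-tailed).  ``aa_ratio`` scales the mean
    acceptor-excitation count relative to the budget; 0 models a
    donor-only species.
    """

    name: str
    true_e: float
    fraction: float
    mean_burst_size: float = 80.0
    burst_size_shape: float = 0.45
    aa_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_e <= 1.0:
            raise ValueError(f"true_e must lie in [0, 1], got {self.true_e}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must lie in [0, 1], got {self.fraction}")
        if not self.mean_burst_size > 0:
            raise ValueError("mean_burst_size must be positive")
        if self.burst_size_shape < 0 or self.aa_ratio < 0:
            raise ValueError("burst_size_shape and aa_ratio must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated acquisition.

    Rates are per second; ``pie_period_ns`` records the excitation
    repetition period (31.25 ns = 32 MHz) as metadata — donor/acceptor
    alternation is represented by the excitation-slot label on each photon,
    not by timestamp parity.
    """

    species: tuple[SpeciesSpec, ...] = ()
    duration_s: float = 60.0
    burst_rate: float = 20.0
    background_dd: float = 500.0
    background_da: float = 500.0
    background_aa: float = 500.0
    correction: CorrectionParams = field(default_factory=CorrectionParams)
    pie_period_ns: float = 31.25
    dwell_mean_ms: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration must be positive")
        for r in (self.burst_rate, self.background_dd, self.background_da,
                  self.background_aa):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if not self.pie_period_ns > 0:
            raise ValueError("pie_period_ns must be positive")
        if self.species:
            total = sum(s.fraction for s in self.species)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"species fractions sum to {total}, expected 1")


@dataclass
class PhotonStream:
    """Timestamped photon events with detection channel and PIE slot.

    ``timestamps_ns`` are non-decreasing; ``channels`` and ``excitations``
    hold the integer values of :class:`Channel` and :class:`Excitation`.
    (donor emission, acceptor excitation) events may be present but are
    ignored by the burst pipeline.
    """

    timestamps_ns: np.ndarray
    channels: np.ndarray
    excitations: np.ndarray
    metadata: SimConfig | str | None = None

    def __post_init__(self) -> None:
        if not (len(self.timestamps_ns) == len(self.channels) == len(self.excitations)):
            raise ValueError("event arrays must have equal length")
        if len(self.timestamps_ns) > 1 and np.any(np.diff(self.timestamps_ns) < 0):
            raise ValueError("timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.timestamps_ns)


def expected_counts(
    spec: SpeciesSpec,
    budget: float,
    params: CorrectionParams,
) -> tuple[float, float, float]:
    """Exact (F_DD, F_DA, F_AA) expectations the simulator targets.

    Applying :func:`vtcfret.burst.corrected_efficiency` to these
    expectations recovers ``spec.true_e`` to machine precision — the
    round-trip identity the generative model is built on.
    """
    if not budget > 0:
        raise ValueError("budget must be positive")
    e = spec.true_e
    f_aa = spec.aa_ratio * budget
    denom = (1.0 - e) * (1.0 + params.lk) + params.gamma * e
    c = (budget - params.di * f_aa) / denom
    if c < 0:
        raise ValueError("direct-excitation contribution exceeds the photon budget")
    f_dd = c * (1.0 - e)
    f_da = c * (params.gamma * e + params.lk * (1.0 - e)) + params.di * f_aa
    return f_dd, f_da, f_aa


def _lognormal_budget(rng, mean: float, shape: float, n: int) -> np.ndarray:
    if shape == 0:
        return np.full(n, max(1, round(mean)), dtype=np.int64)
    mu = np.log(mean) - 0.5 * shape**2
    draws = rng.lognormal(mu, shape, n)
    return np.maximum(1, np.rint(draws)).astype(np.int64)


def simulate_stream(config: SimConfig) -> PhotonStream:
    """Generate one synthetic acquisition.

    Transits arrive as a Poisson process at ``burst_rate``; each draws a
    species by fraction, a photon budget, and per-channel counts under the
    generative model described in the module docstring.  Background photons
    are Poisson and uniform in time per stream.  Identical config and seed
    give a byte-identical event list.
    """
    rng = np.random.default_rng(config.seed)
    pieces_t: list[np.ndarray] = []
    pieces_ch: list[np.ndarray] = []
    pieces_ex: list[np.ndarray] = []
    dur_ns = config.duration_s * 1e9
    p = config.correction

    if config.species:
        n_transits = rng.poisson(config.burst_rate * config.duration_s)
        starts = np.sort(rng.uniform(0, dur_ns, n_transits))
        fracs = np.array([s.fraction for s in config.species])
        which = rng.choice(len(config.species), size=n_transits, p=fracs)
        dwell = rng.exponential(config.dwell_mean_ms * 1e6, n_transits)
        for t0, k, dw in zip(starts, which, dwell):
            sp = config.species[k]
            b = int(_lognormal_budget(rng, sp.mean_burst_size, sp.burst_size_shape, 1)[0])
            f_aa = int(rng.poisson(sp.aa_ratio * b))
            e = sp.true_e
            denom = (1.0 - e) * (1.0 + p.lk) + p.gamma * e
            c = max(0.0, (b - p.di * f_aa) / denom)
            p_da = (c * (p.gamma * e + p.lk * (1.0 - e)) + p.di * f_aa) / b
            f_da = int(rng.binomial(b, min(1.0, max(0.0, p_da))))
            f_dd = b - f_da
            n_ev = f_dd + f_da + f_aa
            ts = t0 + rng.uniform(0, dw, n_ev)
            ch = np.concatenate([
                np.zeros(f_dd, dtype=np.int8),
                np.ones(f_da + f_aa, dtype=np.int8),
            ])
            ex = np.concatenate([
                np.zeros(f_dd + f_da, dtype=np.int8),
                np.ones(f_aa, dtype=np.int8),
            ])
            pieces_t.append(ts)
            pieces_ch.append(ch)
            pieces_ex.append(ex)

    bg_spec = [
        (config.background_dd, Channel.DONOR_EM, Excitation.DONOR_EX),
        (config.background_da, Channel.ACCEPTOR_EM, Excitation.DONOR_EX),
        (config.background_aa, Channel.ACCEPTOR_EM, Excitation.ACCEPTOR_EX),
    ]
    for rate, ch, ex in bg_spec:
        n = rng.poisson(rate * config.duration_s)
        pieces_t.append(rng.uniform(0, dur_ns, n))
        pieces_ch.append(np.full(n, ch.value, dtype=np.int8))
        pieces_ex.append(np.full(n, ex.value, dtype=np.int8))

    ts = np.concatenate(pieces_t) if pieces_t else np.zeros(0)
    ch = np.concatenate(pieces_ch) if pieces_ch else np.zeros(0, dtype=np.int8)
    ex = np.concatenate(pieces_ex) if pieces_ex else np.zeros(0, dtype=np.int8)
    order = np.argsort(ts, kind="stable")
    ts_ns = np.rint(ts[order]).astype(np.int64)
    # rounding to integer ns can swap ties; enforce monotonicity
    ts_ns = np.maximum.accumulate(ts_ns)
    return PhotonStream(ts_ns, ch[order], ex[order], metadata=config)


# ---------------------------------------------------------------------------
# IO

_CH_LABEL = {Channel.DONOR_EM.value: "em_D", Channel.ACCEPTOR_EM.value: "em_A"}
_EX_LABEL = {Excitation.DONOR_EX.value: "ex_D", Excitation.ACCEPTOR_EX.value: "ex_A"}
_CH_VALUE = {v: k for k, v in _CH_LABEL.items()}
_EX_VALUE = {v: k for k, v in _EX_LABEL.items()}


def write_photon_table(stream: PhotonStream, path) -> None:
    """Write a photon stream as TSV: ``timestamp_ns  channel  excitation``."""
    df = pd.DataFrame(
        {
            "timestamp_ns": stream.timestamps_ns,
            "channel": [_CH_LABEL[c] for c in stream.channels],
            "excitation": [_EX_LABEL[e] for e in stream.excitations],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_photon_table(path) -> PhotonStream:
    df = pd.read_csv(path, sep="\t")
    required = {"timestamp_ns", "channel", "excitation"}
    if not required <= set(df.columns):
        raise ValueError(f"photon table must have columns {sorted(required)}")
    try:
        ch = df["channel"].map(_CH_VALUE).astype(np.int8).to_numpy()
        ex = df["excitation"].map(_EX_VALUE).astype(np.int8).to_numpy()
    except (ValueError, TypeError) as err:
        raise ValueError(f"unrecognized channel/excitation label: {err}") from None
    return PhotonStream(
        df["timestamp_ns"].to_numpy(np.int64), ch, ex, metadata=str(path)
    )


_SCALAR_KEYS = {
    "duration_s": float,
    "burst_rate": float,
    "background_dd": float,
    "background_da": float,
    "background_aa": float,
    "lk": float,
    "di": float,
    "gamma": float,
    "r0": float,
    "pie_period_ns": float,
    "dwell_mean_ms": float,
    "seed": int,
}
_SPECIES_KEYS = {
    "name": str,
    "true_e": float,
    "fraction": float,
    "mean_burst_size": float,
    "burst_size_shape": float,
    "aa_ratio": float,
}


def read_sim_config(path) -> SimConfig:
    """Parse a flat ``key = value`` simulation config.

    Scalar keys: duration_s, burst_rate, background_dd/da/aa, lk, di, gamma,
    r0, pie_period_ns, dwell_mean_ms, seed.  Species are declared as
    ``species.<n>.<field>`` with fields name, true_e, fraction,
    mean_burst_size, burst_size_shape, aa_ratio.  Unknown keys are rejected;
    omitted keys take the documented defaults.
    """
    scalars: dict = {}
    species_raw: dict[int, dict] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = (t.strip() for t in line.partition("="))
        if key.startswith("species."):
            try:
                _, idx, fld = key.split(".", 2)
                idx = int(idx)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad species key {key!r}") from None
            if fld not in _SPECIES_KEYS:
                raise ValueError(f"{path}:{lineno}: unknown species field {fld!r}")
            species_raw.setdefault(idx, {})[fld] = _SPECIES_KEYS[fld](value)
        elif key in _SCALAR_KEYS:
            scalars[key] = _SCALAR_KEYS[key](value)
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")

    corr = CorrectionParams(
        lk=scalars.pop("lk", 0.13),
        di=scalars.pop("di", 0.06),
        gamma=scalars.pop("gamma", 0.47),
        r0=scalars.pop("r0", 52.0),
    )
    species = tuple(
        SpeciesSpec(**{"name": f"species{idx}", **fields})
        for idx, fields in sorted(species_raw.items())
    )
    return SimConfig(species=species, correction=corr, **scalars)
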