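"""Synthetic daily count tables with planted longitudinal regimes.

The generator emulates the structure of a dense single-subject gut
time series so every pipeline stage can be exercised, with ground
truth, on data built at run time.  Six regime constructions:

* **stable prevalent** — stationary AR(1) log-abundance around a high
  mean, always present.  The AR coefficient defaults to 0.78: an AR(1)
  power spectrum has flatness 1 - phi^2, so planted stable taxa sit
  well below the 0.4 noise threshold while remaining detectably
  stationary to ADF/KPSS at a 200-day span.
* **unstable prevalent** — a driftless Gaussian random walk in log
  space (a unit root), with a wide safety clip that almost never
  binds.
* **stable temporal** — the AR(1) dynamic gated by a persistent
  two-state Markov presence process targeting mid-band occupancy.
* **unstable temporal** — a colonization/extinction window: the taxon
  is absent for a contiguous leading or trailing block and follows a
  random walk while present.  (Gating a walk day-by-day would destroy
  its unit-root signature; a contiguous window preserves it.)
* **rare** — zero baseline with one to three short, smooth bursts.
* **white noise** — sparse iid Poisson counts.

Within the two prevalent regimes, taxa load on a shared latent factor
with alternating signs, making each regime a block of mutually
proportional (or anti-proportional) trajectories — the planted
structure that co-occurrence graphs should recover.  Each block's
expected daily total is normalized to a constant so that rarefaction
ratios stay stable and the blocks do not leak common-mode variation
into every other taxon through compositional closure.

Latent log-abundances are emitted as Poisson counts, giving
overdispersed (log-normal mixed) integer data.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import skbio

from .table import AbundanceSeriesTable

__all__ = ["SyntheticSpec", "simulate_regime_series", "simulate_subject", "random_tree"]

_REGIMES = (
    "stable_prevalent",
    "unstable_prevalent",
    "stable_temporal",
    "unstable_temporal",
    "rare",
    "white_noise",
)


@dataclasses.dataclass
class SyntheticSpec:
    """Study conditions for one synthetic subject.

    Defaults give a 200-day table with ten taxa per regime: a desk-
    scale analogue of year-long daily 16S series (hundreds of days,
    dominated in counts by a few prevalent taxa, in numbers by rare
    and noisy ones).
    """

    n_days: int = 200
    n_per_regime: dict | None = None
    # stable dynamics
    ar_phi: float = 0.78
    ar_sigma: float = 0.25
    stable_block_total: float = 20_000.0
    factor_phi: float = 0.7
    factor_weight: float = 1.5
    # unstable dynamics
    walk_sigma: float = 0.06
    walk_factor_sigma: float = 0.08
    unstable_block_total: float = 10_000.0
    # temporal occupancy
    temporal_log_mean: float = 5.7  # ~300 reads/day when present
    presence_stay: float = 0.88
    window_frac: tuple = (0.3, 0.75)
    window_log_mean: float = 5.0
    window_walk_sigma: float = 0.09
    # rare bursts
    burst_prob: float = 0.008
    burst_peak: float = 150.0
    # white noise emission
    noise_presence: float = 0.3
    noise_mean_count: float = 6.0
    # seasonality
    seasonal_periods: tuple = (7.5,)
    seasonal_amplitude: float = 0.7
    temporal_seasonal_amplitude: float = 0.45  # community-level rhythm carrier
    n_seasonal: int = 3  # stable-prevalent taxa that also carry a sinusoid
    mask_fraction: float = 0.0  # interior days removed to exercise interpolation
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_regime is None:
            self.n_per_regime = {r: 10 for r in _REGIMES}
        unknown = set(self.n_per_regime) - set(_REGIMES)
        if unknown:
            raise ValueError(f"unknown regimes in spec: {sorted(unknown)}")
        if not (0 <= self.mask_fraction < 0.5):
            raise ValueError("mask_fraction must be in [0, 0.5)")
        if abs(self.ar_phi) >= 1 or abs(self.factor_phi) >= 1:
            raise ValueError("AR coefficients must satisfy |phi| < 1")


def _ar1(rng, n, phi, sigma):
    x = np.empty(n)
    x[0] = rng.normal(0, sigma / np.sqrt(1 - phi**2))
    eps = rng.normal(0, sigma, n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


def _walk(rng, n, sigma):
    return np.cumsum(np.concatenate([[0.0], rng.normal(0, sigma, n - 1)]))


def _markov_gate(rng, n, p_stay):
    present = np.empty(n, bool)
    present[0] = rng.random() < 0.5
    flips = rng.random(n)
    for t in range(1, n):
        present[t] = present[t - 1] if flips[t] < p_stay else not present[t - 1]
    return present


def _seasonal_wave(rng, n, spec: SyntheticSpec, phase: float | None = None,
                   amplitude: float | None = None):
    t = np.arange(n)
    amp = spec.seasonal_amplitude if amplitude is None else amplitude
    wave = np.zeros(n)
    for period in spec.seasonal_periods:
        wave += amp * np.sin(
            2 * np.pi * t / period
            + (rng.uniform(0, 2 * np.pi) if phase is None else phase)
        )
    return wave


def simulate_regime_series(
    regime: str,
    spec: SyntheticSpec,
    seed: int,
    shared_factor: np.ndarray | None = None,
    factor_sign: float = 1.0,
    seasonal: bool = False,
    phase: float | None = None,
) -> tuple[np.ndarray, dict]:
    """One standalone taxon trajectory plus its ground-truth record.

    ``shared_factor`` (optional, same length as the series) is added to
    the log-abundance with sign ``factor_sign`` to create proportional
    blocks; :func:`simulate_subject` additionally normalizes block
    totals, which this per-series entry point does not do.
    """
    if regime not in _REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    n = spec.n_days
    amp = (
        spec.temporal_seasonal_amplitude
        if regime == "stable_temporal"
        else spec.seasonal_amplitude
    )
    season = (
        _seasonal_wave(rng, n, spec, phase=phase, amplitude=amp)
        if seasonal
        else np.zeros(n)
    )

    if regime == "stable_prevalent":
        latent = 7.6 + _ar1(rng, n, spec.ar_phi, spec.ar_sigma) + season
        if shared_factor is not None:
            latent = latent + factor_sign * spec.factor_weight * shared_factor
        counts = np.maximum(rng.poisson(np.exp(np.clip(latent, 0, 11))), 1)
    elif regime == "unstable_prevalent":
        latent = 6.9 + np.clip(_walk(rng, n, spec.walk_sigma), -2.8, 2.8) + season
        if shared_factor is not None:
            latent = latent + factor_sign * shared_factor
        counts = np.maximum(rng.poisson(np.exp(np.clip(latent, 0, 11))), 1)
    elif regime == "stable_temporal":
        latent = spec.temporal_log_mean + _ar1(rng, n, spec.ar_phi, spec.ar_sigma)
        gate = _markov_gate(rng, n, spec.presence_stay)
        tries = 0  # regenerate degenerate all-on/all-off gates
        while not (0.15 <= gate.mean() <= 0.85) and tries < 20:
            gate = _markov_gate(rng, n, spec.presence_stay)
            tries += 1
        counts = rng.poisson(np.exp(latent + season)) * gate
    elif regime == "unstable_temporal":
        frac = rng.uniform(*spec.window_frac)
        m = max(int(n * frac), 20)
        segment = np.maximum(
            rng.poisson(
                np.exp(
                    spec.window_log_mean
                    + np.clip(_walk(rng, m, spec.window_walk_sigma), -2.5, 2.5)
                    + season[:m]
                )
            ),
            1,
        )
        counts = np.zeros(n, dtype=np.int64)
        if rng.random() < 0.5:
            counts[:m] = segment  # extinction: present then gone
        else:
            counts[n - m :] = segment  # colonization: appears mid-series
    elif regime == "rare":
        counts = np.zeros(n, dtype=np.int64)
        starts = np.where(rng.random(n) < spec.burst_prob)[0]
        if len(starts) == 0:
            starts = np.array([rng.integers(0, n - 8)])
        for s in starts[:3]:  # cap bursts so prevalence stays < 10%
            length = int(rng.integers(4, 8))
            bump = np.sin(np.linspace(0, np.pi, length)) * spec.burst_peak
            end = min(s + length, n)
            counts[s:end] += rng.poisson(bump[: end - s])
    else:  # white_noise
        gate = rng.random(n) < spec.noise_presence
        counts = rng.poisson(spec.noise_mean_count, n) * gate
    truth = {
        "regime": regime,
        "seasonal": bool(seasonal),
        "prevalence": float((counts > 0).mean()),
    }
    return counts.astype(np.int64), truth


def _block(spec, rng, regime, n_taxa, factor, total, phase=None):
    """Latent block with alternating factor signs, normalized so the
    expected daily block total is constant.  Seasonal taxa within a
    subject share one phase so their rhythms stay coherent at the
    community level."""
    n = spec.n_days
    latents, seasonal_flags = [], []
    for i in range(n_taxa):
        r = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
        sign = 1.0 if i % 2 == 0 else -1.0
        seasonal = regime == "stable_prevalent" and i < spec.n_seasonal
        # alternate the seasonal sign so the rhythm survives in relative
        # composition (a common multiplicative rhythm would be removed
        # by closure/rarefaction)
        season = (
            sign * _seasonal_wave(r, n, spec, phase=phase) if seasonal else 0.0
        )
        if regime == "stable_prevalent":
            own = _ar1(r, n, spec.ar_phi, spec.ar_sigma)
            lat = own + sign * spec.factor_weight * factor + season
        else:
            own = _walk(r, n, spec.walk_sigma)
            lat = own + sign * factor
        latents.append(np.exp(lat))
        seasonal_flags.append(seasonal)
    latents = np.asarray(latents)
    scale = total / latents.sum(axis=0)
    counts = []
    for i in range(n_taxa):
        r = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
        counts.append(np.maximum(r.poisson(latents[i] * scale), 1))
    return counts, seasonal_flags


def simulate_subject(spec: SyntheticSpec) -> tuple[AbundanceSeriesTable, pd.DataFrame]:
    """Assemble a full subject table with per-ASV ground-truth labels.

    Reproducible: the same spec (including seed) yields an identical
    table.  When ``mask_fraction`` > 0, that fraction of interior days
    is removed so the interpolation stage has work to do.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_days
    factor_stable = _ar1(rng, n, spec.factor_phi, spec.ar_sigma)
    factor_unstable = _walk(rng, n, spec.walk_factor_sigma)
    seasonal_phase = float(rng.uniform(0, 2 * np.pi))
    columns, truth_rows = {}, []
    counter = 0

    def _add(counts, regime, seasonal):
        nonlocal counter
        asv = f"ASV_{counter:04d}"
        counter += 1
        columns[asv] = counts
        truth_rows.append(
            {
                "asv_id": asv,
                "regime": regime,
                "seasonal": bool(seasonal),
                "prevalence": float((counts > 0).mean()),
            }
        )

    for regime, factor, total in (
        ("stable_prevalent", factor_stable, spec.stable_block_total),
        ("unstable_prevalent", factor_unstable, spec.unstable_block_total),
    ):
        n_taxa = spec.n_per_regime.get(regime, 0)
        if n_taxa:
            counts_list, seas = _block(
                spec, rng, regime, n_taxa, factor, total, phase=seasonal_phase
            )
            for c, s in zip(counts_list, seas):
                _add(c.astype(np.int64), regime, s)
    for regime in ("stable_temporal", "unstable_temporal", "rare", "white_noise"):
        for _ in range(spec.n_per_regime.get(regime, 0)):
            # stable-temporal taxa share the subject's seasonal phase so
            # the planted rhythm survives at the community level (their
            # counts are not block-normalized, so a coherent swing
            # shifts their share of the day total)
            modulated = regime == "stable_temporal"
            counts, truth = simulate_regime_series(
                regime,
                spec,
                seed=int(rng.integers(0, 2**31 - 1)),
                seasonal=modulated,
                phase=seasonal_phase if modulated else None,
            )
            _add(counts, regime, truth["seasonal"])

    df = pd.DataFrame(columns, index=np.arange(n))
    if spec.mask_fraction > 0:
        interior = np.arange(1, n - 1)
        n_drop = int(round(spec.mask_fraction * n))
        drop = np.sort(rng.choice(interior, size=n_drop, replace=False))
        df = df.drop(index=drop)
    table = AbundanceSeriesTable(df, subject_id=f"synthetic-{spec.rng_seed}")
    truth = pd.DataFrame(truth_rows).set_index("asv_id")
    return table, truth


def random_tree(asv_ids, seed: int = 0) -> skbio.TreeNode:
    """A random rooted bifurcating tree over the given tips, with
    exponential branch lengths — a companion input for Faith's PD."""
    rng = np.random.default_rng(seed)
    nodes = [skbio.TreeNode(name=a, length=float(rng.exponential(0.5))) for a in asv_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), 2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = skbio.TreeNode(length=float(rng.exponential(0.5)))
        parent.extend([a, b])
        nodes = [x for x in nodes if x is not a and x is not b] + [parent]
    root = nodes[0]
    root.length = None
    return root
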