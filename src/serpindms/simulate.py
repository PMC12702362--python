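"""Synthetic two-timepoint phage-display selection screen.

The generator states a complete world for the analysis pipeline: a
site-saturation library over an L-residue metastable serpin (19 substitutions
per site), selection for protease inhibition at 0 h and again after a 48 h
incubation during which each variant decays out of its active conformation
with first-order kinetics, negative-binomial sequencing noise, predictor
tables correlated with function but not half-life, and per-position
conservation scores tied to positional tolerance for both functions.

Selection model
---------------
A variant is captured by the protease selection in proportion to its
inhibitory activity ``a`` times the fraction still in the active conformation
after ``t`` hours of incubation::

    p_i(t) = a_i * 2 ** (-t / h_i)

with ``h_i`` the latency half-life in hours (wild-type 1-2 h).  Post-selection
frequencies are the input frequencies reweighted by ``p`` and renormalized.
Exponential decay makes the selection compose: selecting at t1 then t2 with
a = 1 equals one selection at t1 + t2.

All randomness flows through a single seeded :class:`numpy.random.Generator`;
draws happen in a fixed, documented order (wild-type sequence, per-position
tolerances, presence mask, functional mask, activities, half-lives,
stabilization mask, then counts / predictors / conservation as requested).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateSelectionError
from .variants import AMINO_ACIDS, Variant, parse_variant

_FREQ_TOL = 1e-6

CONDITION_INPUT = "input"


def condition_label(t_hours: float) -> str:
    """Condition label for a selection timepoint, e.g. ``sel0h``, ``sel48h``."""
    if float(t_hours).is_integer():
        return f"sel{int(t_hours)}h"
    return f"sel{t_hours:g}h"


@dataclass(frozen=True)
class SimConfig:
    """Stated world of the synthetic screen.

    Defaults mirror the screen being emulated: a 379-residue protein, ~96%
    library coverage, two spike-ins (I91L at 2.6%, E242T at 1.4%), wild-type
    latency half-life uniform on 1-2 h, stabilized variants 20x slower,
    sequencing depth 2e6 with 3 replicates per condition and NB
    overdispersion 0.05, and five planted stabilizing regions.

    Activity of functional variants is log-uniform on
    ``functional_activity_range`` (enrichment of functional variants spreads
    over about two log2 units, as in real screens); nonfunctional variants get
    activity log-uniform on ``nonfunctional_activity_range`` (near zero but
    positive, so they deplete rather than vanish).  Per-position tolerance
    ``tol0`` (fraction of substitutions functional) is Beta-distributed;
    ``tol48`` (fraction of substitutions stabilizing) is high inside planted
    regions and low outside.
    """

    L: int = 379
    missing_fraction: float = 0.045
    depth: int = 2_000_000
    replicates: int = 3
    dispersion: float = 0.05
    incubation_times: tuple[float, ...] = (0.0, 48.0)
    spike_ins: tuple[tuple[str, float], ...] = (("I91L", 0.026), ("E242T", 0.014))
    seed: int = 0
    wt_half_life_range: tuple[float, float] = (1.0, 2.0)
    stabilized_half_life_multiplier: float = 20.0
    functional_activity_range: tuple[float, float] = (0.25, 1.0)
    nonfunctional_activity_range: tuple[float, float] = (0.001, 0.02)
    tol0_beta_params: tuple[float, float] = (2.0, 2.0)
    tol0_fixed: float | None = None
    tol48_in_region: float = 0.7
    tol48_background: float = 0.1
    weak_stabilized_fraction: float = 0.5
    weak_half_life_multiplier: float = 4.0
    planted_regions: tuple[tuple[int, int], ...] = (
        (40, 45), (72, 93), (158, 178), (216, 237), (320, 347),
    )
    conservation_alpha: float = 1.3
    conservation_beta: float = 0.73
    conservation_noise_sd: float = 0.3
    vep_noise_sd: float = 0.05
    ddg_baseline_active: float = 0.5
    ddg_baseline_latent: float = 0.8
    misfolding_penalty: float = 2.5
    ddg_noise_sd: float = 0.5

    def __post_init__(self):
        if self.L < 1:
            raise ConfigurationError(f"L must be >= 1, got {self.L}")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ConfigurationError(
                f"missing_fraction must be in [0, 1], got {self.missing_fraction}"
            )
        if self.depth <= 0:
            raise ConfigurationError(f"depth must be > 0, got {self.depth}")
        if self.replicates < 1:
            raise ConfigurationError(f"replicates must be >= 1, got {self.replicates}")
        if self.dispersion < 0:
            raise ConfigurationError(f"dispersion must be >= 0, got {self.dispersion}")
        if self.stabilized_half_life_multiplier < 1:
            raise ConfigurationError("stabilized_half_life_multiplier must be >= 1")
        total_spike = 0.0
        for name, freq in self.spike_ins:
            v = parse_variant(name)
            if v.position > self.L:
                raise ConfigurationError(
                    f"spike-in {name} beyond protein length L={self.L}"
                )
            if not 0.0 <= freq <= 1.0:
                raise ConfigurationError(f"spike-in frequency {freq} outside [0, 1]")
            total_spike += freq
        if total_spike >= 1.0:
            raise ConfigurationError("spike-in frequencies must sum to < 1")
        for lo, hi in self.planted_regions:
            if not (1 <= lo <= hi <= self.L):
                raise ConfigurationError(
                    f"planted region ({lo}, {hi}) outside 1..{self.L}"
                )
        for name, pair in (
            ("wt_half_life_range", self.wt_half_life_range),
            ("functional_activity_range", self.functional_activity_range),
            ("nonfunctional_activity_range", self.nonfunctional_activity_range),
        ):
            lo, hi = pair
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} must satisfy 0 < low <= high")
        for name, val in (
            ("tol48_in_region", self.tol48_in_region),
            ("tol48_background", self.tol48_background),
        ):
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {val}")
        if not 0.0 <= self.weak_stabilized_fraction <= 1.0:
            raise ConfigurationError("weak_stabilized_fraction must be in [0, 1]")
        if self.weak_half_life_multiplier < 1:
            raise ConfigurationError("weak_half_life_multiplier must be >= 1")
        if self.conservation_alpha < 0 or self.conservation_beta < 0:
            raise ConfigurationError("conservation alpha and beta must be >= 0")
        if any(t < 0 for t in self.incubation_times):
            raise ConfigurationError("incubation times must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A fully null world: every variant wild-type-like.

    All activities equal, all half-lives equal, no planted regions and no
    spike-ins, so every true log2 fold change is zero under both contrasts.
    Used for false-discovery-rate calibration.
    """
    base = dict(
        seed=seed,
        tol0_fixed=1.0,
        functional_activity_range=(1.0, 1.0),
        wt_half_life_range=(1.5, 1.5),
        stabilized_half_life_multiplier=1.0,
        planted_regions=(),
        tol48_background=0.0,
        weak_stabilized_fraction=0.0,
        spike_ins=(),
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class GroundTruth:
    """Per-variant and per-position truth underlying one simulated screen.

    Attributes
    ----------
    wt_seq : str
        Synthetic wild-type sequence (length L).
    variants : pandas.DataFrame
        Indexed by variant string; columns ``position``, ``wt_aa``, ``alt_aa``,
        ``present``, ``functional``, ``stabilized``, ``activity``,
        ``half_life``.
    positions : pandas.DataFrame
        Indexed by 1-based position; columns ``tol0``, ``tol48``,
        ``in_region``.
    planted_regions : tuple of (start, end)
        1-based inclusive stabilizing intervals.
    """

    wt_seq: str
    variants: pd.DataFrame
    positions: pd.DataFrame
    planted_regions: tuple[tuple[int, int], ...]
    config: SimConfig = field(repr=False, default=None)

    @property
    def present(self) -> pd.DataFrame:
        return self.variants[self.variants["present"]]


def _region_mask(L: int, regions) -> np.ndarray:
    mask = np.zeros(L, dtype=bool)
    for lo, hi in regions:
        mask[lo - 1 : hi] = True
    return mask


def generate_ground_truth(
    config: SimConfig, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Draw the library composition and every variant's (activity, half-life).

    Exactly ``19 * L`` candidate variants are enumerated; a seeded random
    subset of size ``ceil((1 - missing_fraction) * 19L)`` is marked present.
    A variant is functional with its position's probability ``tol0``;
    functional variants inside planted regions are additionally stabilized
    (half-life multiplied by ``stabilized_half_life_multiplier``) with
    probability ``tol48`` of their position.
    """
    if rng is None:
        rng = config.rng()
    L = config.L

    # 1. wild-type sequence; spike-in positions forced to their stated residue
    wt = rng.choice(list(AMINO_ACIDS), size=L)
    for name, _freq in config.spike_ins:
        v = parse_variant(name)
        wt[v.position - 1] = v.wt_aa
    wt_seq = "".join(wt)

    # 2. per-position tolerances
    if config.tol0_fixed is not None:
        tol0 = np.full(L, float(config.tol0_fixed))
    else:
        a, b = config.tol0_beta_params
        tol0 = rng.beta(a, b, size=L)
    in_region = _region_mask(L, config.planted_regions)
    tol48 = np.where(in_region, config.tol48_in_region, config.tol48_background)

    positions = pd.DataFrame(
        {"tol0": tol0, "tol48": tol48, "in_region": in_region},
        index=pd.RangeIndex(1, L + 1, name="position"),
    )

    # 3. candidate variants (19 per site, fixed enumeration order)
    pos_arr = np.repeat(np.arange(1, L + 1), len(AMINO_ACIDS) - 1)
    wt_arr = np.repeat(list(wt_seq), len(AMINO_ACIDS) - 1)
    alt_arr = np.concatenate(
        [[aa for aa in AMINO_ACIDS if aa != wt_seq[p]] for p in range(L)]
    )
    n = len(pos_arr)  # 19 * L

    # 4. presence mask
    n_present = math.ceil((1.0 - config.missing_fraction) * n)
    present = np.zeros(n, dtype=bool)
    present[rng.choice(n, size=n_present, replace=False)] = True
    # spike-ins are always in the library
    names = np.char.add(np.char.add(wt_arr, pos_arr.astype(str)), alt_arr)
    name_to_idx = {s: i for i, s in enumerate(names)}
    for name, _freq in config.spike_ins:
        present[name_to_idx[str(parse_variant(name))]] = True

    # 5. functional mask, 6. activities (log-uniform within class)
    functional = rng.random(n) < tol0[pos_arr - 1]

    def _log_uniform(lo, hi, size):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))

    act_fun = _log_uniform(*config.functional_activity_range, n)
    act_non = _log_uniform(*config.nonfunctional_activity_range, n)
    activity = np.where(functional, act_fun, act_non)

    # 7. half-lives, 8. strong stabilization (planted regions),
    # 9. weak stabilization (position-independent graded kinetic effects:
    #    modest half-life prolongation among functional variants anywhere,
    #    which keeps the 48 h selected pool from collapsing onto the strong
    #    stabilizers alone)
    half_life = rng.uniform(*config.wt_half_life_range, size=n)
    stabilized = functional & in_region[pos_arr - 1] & (
        rng.random(n) < tol48[pos_arr - 1]
    )
    weak = (
        functional
        & ~stabilized
        & (rng.random(n) < config.weak_stabilized_fraction)
    )
    half_life = np.where(
        stabilized,
        half_life * config.stabilized_half_life_multiplier,
        np.where(weak, half_life * config.weak_half_life_multiplier, half_life),
    )

    variants = pd.DataFrame(
        {
            "position": pos_arr,
            "wt_aa": wt_arr,
            "alt_aa": alt_arr,
            "present": present,
            "functional": functional,
            "stabilized": stabilized,
            "weak_stabilized": weak,
            "activity": activity,
            "half_life": half_life,
        },
        index=pd.Index(names, name="variant"),
    )
    return GroundTruth(wt_seq, variants, positions, tuple(config.planted_regions), config)


def input_frequencies(truth: GroundTruth) -> pd.Series:
    """Input library frequencies: near-equal representation of present
    variants, with configured spike-ins overriding their own frequency."""
    config = truth.config
    present = truth.present
    spikes = {str(parse_variant(name)): f for name, f in config.spike_ins}
    spike_total = sum(spikes.values())
    n_other = len(present) - len(spikes)
    if n_other < 0 or (n_other == 0 and spike_total < 1.0 - _FREQ_TOL):
        raise ConfigurationError("library has no non-spike-in variants")
    base = (1.0 - spike_total) / n_other if n_other else 0.0
    freqs = pd.Series(base, index=present.index, name="frequency")
    for name, f in spikes.items():
        freqs.loc[name] = f
    return freqs


def simulate_selection(
    truth_or_activity,
    half_life=None,
    input_freqs=None,
    t: float = 0.0,
) -> pd.Series | np.ndarray:
    """Expected post-selection frequencies after ``t`` hours of incubation.

    ``f_sel_i = f_in_i * p_i(t) / sum_j f_in_j * p_j(t)`` with
    ``p_i(t) = a_i * 2**(-t/h_i)``.  Accepts either a :class:`GroundTruth`
    (with ``input_freqs`` aligned to its present variants) or raw arrays
    ``(activity, half_life, input_freqs, t)``.
    """
    if isinstance(truth_or_activity, GroundTruth):
        present = truth_or_activity.present
        activity = present["activity"].to_numpy()
        hl = present["half_life"].to_numpy()
        f_in = np.asarray(input_freqs.reindex(present.index), dtype=float)
        index = present.index
    else:
        activity = np.asarray(truth_or_activity, dtype=float)
        hl = np.asarray(half_life, dtype=float)
        f_in = np.asarray(input_freqs, dtype=float)
        index = None
    if t < 0:
        raise ConfigurationError(f"incubation time must be >= 0, got {t}")
    if abs(f_in.sum() - 1.0) > _FREQ_TOL:
        raise ConfigurationError(
            f"input frequencies must sum to 1 (got {f_in.sum():.6g})"
        )
    p = activity * np.exp2(-t / hl) if t > 0 else activity.copy()
    total = float((f_in * p).sum())
    if total <= 0.0:
        raise DegenerateSelectionError(
            f"all capture probabilities vanish at t={t} h"
        )
    f_sel = f_in * p / total
    if index is not None:
        return pd.Series(f_sel, index=index, name=f"freq_t{t:g}h")
    return f_sel


def sample_read_counts(
    freqs,
    config: SimConfig,
    condition: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sequencing counts for one condition, one column per replicate.

    ``dispersion == 0`` draws a multinomial at the configured depth;
    ``dispersion > 0`` draws per-variant negative binomials with mean
    ``depth * f_i`` and variance ``mean + dispersion * mean**2`` (so column
    sums match depth only up to sampling error).
    """
    if config.dispersion < 0:
        raise ConfigurationError("dispersion must be >= 0")
    index = freqs.index if isinstance(freqs, pd.Series) else None
    f = np.asarray(freqs, dtype=float)
    if abs(f.sum() - 1.0) > _FREQ_TOL:
        raise ConfigurationError(f"frequencies must sum to 1 (got {f.sum():.6g})")
    cols = {}
    for r in range(1, config.replicates + 1):
        if config.dispersion == 0:
            counts = rng.multinomial(config.depth, f / f.sum())
        else:
            mu = config.depth * f
            size = 1.0 / config.dispersion  # NB "n"; var = mu + mu^2/size
            p = size / (size + mu)
            counts = rng.negative_binomial(size, p)
        cols[f"{condition}_{r}"] = counts.astype(np.int64)
    return pd.DataFrame(cols, index=index)


def generate_predictor_tables(
    truth: GroundTruth,
    vep_noise_sd: float | None = None,
    ddg_noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Variant-effect and folding-stability predictor tables.

    The VEP score is a monotone decreasing function of activity plus Gaussian
    noise, clipped to [0, 1] (higher = more pathogenic).  ddG in both the
    active and latent conformations is a constant baseline plus a misfolding
    penalty for nonfunctional variants plus noise — with *no* dependence on
    half-life, emulating predictors blind to latency kinetics.
    """
    config = truth.config
    if vep_noise_sd is None:
        vep_noise_sd = config.vep_noise_sd
    if ddg_noise_sd is None:
        ddg_noise_sd = config.ddg_noise_sd
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    v = truth.variants
    n = len(v)
    nonfunctional = ~v["functional"].to_numpy()
    vep = 1.0 - v["activity"].to_numpy()
    if vep_noise_sd > 0:
        vep = vep + rng.normal(0.0, vep_noise_sd, size=n)
    vep = np.clip(vep, 0.0, 1.0)
    penalty = config.misfolding_penalty * nonfunctional
    ddg_active = config.ddg_baseline_active + penalty
    ddg_latent = config.ddg_baseline_latent + penalty
    if ddg_noise_sd > 0:
        ddg_active = ddg_active + rng.normal(0.0, ddg_noise_sd, size=n)
        ddg_latent = ddg_latent + rng.normal(0.0, ddg_noise_sd, size=n)
    return pd.DataFrame(
        {
            "position": v["position"],
            "wt_aa": v["wt_aa"],
            "alt_aa": v["alt_aa"],
            "vep_score": vep,
            "ddg_active": ddg_active,
            "ddg_latent": ddg_latent,
        },
        index=v.index,
    )


def generate_conservation_scores(
    truth: GroundTruth,
    alpha: float | None = None,
    beta: float | None = None,
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Per-position conservation scores (higher = more evolutionarily labile).

    ``score_p = alpha * tol0_p - beta * tol48_p + eps_p``: lability rises with
    tolerance to substitution at 0 h and falls where substitutions stabilize,
    planting the sign structure the selection analysis is meant to recover.
    """
    config = truth.config
    if alpha is None:
        alpha = config.conservation_alpha
    if beta is None:
        beta = config.conservation_beta
    if noise_sd is None:
        noise_sd = config.conservation_noise_sd
    if alpha < 0 or beta < 0:
        raise ConfigurationError("alpha and beta must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    pos = truth.positions
    score = alpha * pos["tol0"].to_numpy() - beta * pos["tol48"].to_numpy()
    if noise_sd > 0:
        score = score + rng.normal(0.0, noise_sd, size=len(pos))
    return pd.Series(score, index=pos.index, name="conservation")


@dataclass
class SimulatedScreen:
    """Everything one synthetic run produces."""

    truth: GroundTruth
    counts: pd.DataFrame          # present variants x samples
    samples: pd.DataFrame         # sample, condition, replicate
    predictors: pd.DataFrame      # all candidate variants
    conservation: pd.Series       # per position
    config: SimConfig


def simulate_screen(config: SimConfig) -> SimulatedScreen:
    """Run the full generative model under one seeded RNG.

    Draw order: ground truth, input counts, then counts per incubation time
    (in configured order), then predictor tables, then conservation noise.
    """
    rng = config.rng()
    truth = generate_ground_truth(config, rng)
    f_in = input_frequencies(truth)

    blocks = [sample_read_counts(f_in, config, CONDITION_INPUT, rng)]
    sample_rows = [
        {"sample": f"{CONDITION_INPUT}_{r}", "condition": CONDITION_INPUT, "replicate": r}
        for r in range(1, config.replicates + 1)
    ]
    for t in config.incubation_times:
        label = condition_label(t)
        f_sel = simulate_selection(truth, input_freqs=f_in, t=t)
        blocks.append(sample_read_counts(f_sel, config, label, rng))
        sample_rows += [
            {"sample": f"{label}_{r}", "condition": label, "replicate": r}
            for r in range(1, config.replicates + 1)
        ]
    counts = pd.concat(blocks, axis=1)
    counts.index.name = "variant"
    samples = pd.DataFrame(sample_rows).set_index("sample")

    predictors = generate_predictor_tables(truth, rng=rng)
    conservation = generate_conservation_scores(truth, rng=rng)
    return SimulatedScreen(truth, counts, samples, predictors, conservation, config)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
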