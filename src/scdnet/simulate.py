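"""Simulation study of the intra-state correlation test.

Synthetic gene pairs are drawn in the z-scored domain: signals are standard
normal, a correlated pair is bivariate normal with unit variances and
covariance theta, Gaussian noise of relative power epsilon is added
(attenuating observable correlation by 1/(1+epsilon)), and a tau fraction
of observations is eliminated to mimic scRNA-seq zeros.  Each scenario
generates ``n_pairs`` pairs of which ``frac_correlated`` are truly
correlated, computes the masked Pearson correlation on each pair's support,
Fisher-transforms it to an interaction score, and calls significance against
zero.  Accuracy / sensitivity / specificity against the ground truth make up
the report.

Two decision rules are available:

* the family-wise rule: two-sided normal p, Bonferroni over the testable
  pairs at level alpha (the default); and
* a fixed per-test threshold |I| > z_cut, obtained from
  :func:`calibrate_threshold`, which locates the threshold realizing a
  requested null specificity (the "operating point" of the method).

Elimination is *paired* by default: the same randomly chosen indices are
removed from both genes of a pair, leaving a deterministic support of
K - round(tau * K) (round half away from zero).  An independent per-gene
mode, whose support is the intersection of the survivors, is available via
``elimination="independent"``.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .corrcore import fisher_interaction, intra_state_pvalue
from .preprocess import ValidationError

#: minimum support for the Fisher score (n - 3 >= 1)
MIN_SUPPORT = 4

ELIMINATION_MODES = ("paired", "independent")


def round_half_away(x: float) -> int:
    """round(x) with halves away from zero (0.5 -> 1, 12.5 -> 13)."""
    return int(np.floor(np.abs(x) + 0.5) * np.sign(x)) if x else 0


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation scenario.

    Defaults are the study conditions: 10,000 pairs, 20% correlated,
    covariance ``theta`` for correlated pairs, relative noise power
    ``epsilon``, ``K`` cells, eliminated fraction ``tau``, family-wise level
    ``alpha`` with Bonferroni over the testable pairs.
    """

    n_pairs: int = 10_000
    frac_correlated: float = 0.20
    theta: float = 0.7
    epsilon: float = 0.05
    K: int = 50
    tau: float = 0.25
    alpha: float = 0.05
    seed: int = 0
    n_reps: int = 1
    elimination: str = "paired"
    noise_before_elimination: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.frac_correlated <= 1:
            raise ValidationError("frac_correlated must be in [0, 1]")
        if not 0 <= self.tau < 1:
            raise ValidationError("tau must be in [0, 1)")
        if self.epsilon < 0:
            raise ValidationError("epsilon must be >= 0")
        if self.K < 4:
            raise ValidationError("K must be >= 4")
        if abs(self.theta) > 1:
            raise ValidationError("|theta| must be <= 1 (unit-variance covariance)")
        if self.elimination not in ELIMINATION_MODES:
            raise ValidationError(f"elimination must be one of {ELIMINATION_MODES}")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.n_pairs < 1 or self.n_reps < 1:
            raise ValidationError("n_pairs and n_reps must be >= 1")

    @property
    def n_correlated(self) -> int:
        return round_half_away(self.n_pairs * self.frac_correlated)

    @property
    def n_eliminated(self) -> int:
        return round_half_away(self.tau * self.K)


@dataclass(frozen=True)
class GenePairSample:
    """A single simulated gene pair (mainly for inspection and tests).

    ``kept_x`` / ``kept_y`` mark surviving observations per gene; the pair's
    support is their intersection (identical vectors in paired elimination).
    """

    x: np.ndarray
    y: np.ndarray
    correlated: bool
    kept_x: np.ndarray
    kept_y: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.kept_x & self.kept_y)

    @property
    def untestable(self) -> bool:
        return self.support.size < MIN_SUPPORT


@dataclass(frozen=True)
class SimulationReport:
    """Confusion counts and summary metrics of one scenario.

    Untestable pairs (support < 4) are excluded from tp/fp/tn/fn and counted
    in ``n_untestable`` — they correspond to the dashes of a support-starved
    scenario table.
    """

    config: SimulationConfig
    rule: str
    z_cut: float | None
    tp: int
    fp: int
    tn: int
    fn: int
    n_untestable: int
    n_untestable_correlated: int
    elapsed_seconds: float
    rounding: str = "half-away-from-zero"

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else float("nan")

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    def to_dict(self) -> dict:
        out = asdict(self.config)
        out.update(
            rule=self.rule,
            z_cut=self.z_cut,
            tp=self.tp,
            fp=self.fp,
            tn=self.tn,
            fn=self.fn,
            n_untestable=self.n_untestable,
            n_untestable_correlated=self.n_untestable_correlated,
            accuracy=self.accuracy,
            sensitivity=self.sensitivity,
            specificity=self.specificity,
            elapsed_seconds=self.elapsed_seconds,
            rounding=self.rounding,
        )
        return out


# ---------------------------------------------------------------------------
# Single-pair building blocks
# ---------------------------------------------------------------------------


def generate_pair(
    theta: float, K: int, correlated: bool, rng: np.random.Generator
) -> GenePairSample:
    """Draw one pair of length-K signals, correlated (covariance theta) or not.

    A correlated pair is bivariate normal with unit variances; theta = 1 is
    the degenerate case y == x exactly.
    """
    if abs(theta) > 1:
        raise ValidationError("|theta| must be <= 1")
    x = rng.standard_normal(K)
    if not correlated or theta == 0.0:
        y = rng.standard_normal(K)
    elif abs(theta) == 1.0:
        y = np.sign(theta) * x
        rng.standard_normal(K)  # keep the stream aligned with the generic case
    else:
        y = theta * x + np.sqrt(1.0 - theta**2) * rng.standard_normal(K)
    keep = np.ones(K, dtype=bool)
    return GenePairSample(x=x, y=y, correlated=correlated, kept_x=keep, kept_y=keep.copy())


def add_noise(
    pair: GenePairSample, epsilon: float, rng: np.random.Generator
) -> GenePairSample:
    """Add independent Gaussian noise of relative power epsilon to each gene."""
    if epsilon < 0:
        raise ValidationError("epsilon must be >= 0")
    if epsilon == 0:
        return pair
    s = np.sqrt(epsilon)
    return replace(
        pair,
        x=pair.x + s * rng.standard_normal(pair.x.size),
        y=pair.y + s * rng.standard_normal(pair.y.size),
    )


def apply_elimination(
    pair: GenePairSample, tau: float, rng: np.random.Generator, mode: str = "paired"
) -> GenePairSample:
    """Eliminate a tau fraction of observations (the stand-in for zeros).

    ``paired`` removes the same round(tau*K) uniformly chosen indices from
    both genes; ``independent`` removes round(tau*K) indices per gene
    independently, so the support is the (smaller) intersection.  A pair
    whose support falls below 4 is untestable.
    """
    if not 0 <= tau < 1:
        raise ValidationError("tau must be in [0, 1)")
    if mode not in ELIMINATION_MODES:
        raise ValidationError(f"elimination mode must be one of {ELIMINATION_MODES}")
    K = pair.x.size
    n_drop = round_half_away(tau * K)
    if n_drop == 0:
        return pair
    if mode == "paired":
        drop = rng.choice(K, size=n_drop, replace=False)
        kept = np.ones(K, dtype=bool)
        kept[drop] = False
        return replace(pair, kept_x=kept, kept_y=kept.copy())
    kept_x = np.ones(K, dtype=bool)
    kept_x[rng.choice(K, size=n_drop, replace=False)] = False
    kept_y = np.ones(K, dtype=bool)
    kept_y[rng.choice(K, size=n_drop, replace=False)] = False
    return replace(pair, kept_x=kept_x, kept_y=kept_y)


# ---------------------------------------------------------------------------
# Vectorized dataset generation and scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedDataset:
    """All pairs of one scenario in array form (pairs x cells)."""

    x: np.ndarray
    y: np.ndarray
    kept_x: np.ndarray
    kept_y: np.ndarray
    correlated: np.ndarray  # bool per pair


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate every pair of a scenario (reproducible from config.seed)."""
    rng = np.random.default_rng(config.seed)
    n, K = config.n_pairs, config.K
    n_corr = config.n_correlated
    x = rng.standard_normal((n, K))
    z = rng.standard_normal((n, K))
    y = z.copy()
    th = config.theta
    if n_corr:
        if abs(th) == 1.0:
            y[:n_corr] = np.sign(th) * x[:n_corr]
        elif th != 0.0:
            y[:n_corr] = th * x[:n_corr] + np.sqrt(1.0 - th**2) * z[:n_corr]
    correlated = np.zeros(n, dtype=bool)
    correlated[:n_corr] = True

    def _noise(a, b):
        if config.epsilon > 0:
            s = np.sqrt(config.epsilon)
            a = a + s * rng.standard_normal(a.shape)
            b = b + s * rng.standard_normal(b.shape)
        return a, b

    if config.noise_before_elimination:
        x, y = _noise(x, y)
    n_drop = config.n_eliminated
    if n_drop:
        # per-row uniformly random subset: rank a uniform draw
        order = rng.random((n, K)).argsort(axis=1)
        kept_x = order >= n_drop
        if config.elimination == "paired":
            kept_y = kept_x.copy()
        else:
            kept_y = rng.random((n, K)).argsort(axis=1) >= n_drop
    else:
        kept_x = np.ones((n, K), dtype=bool)
        kept_y = kept_x.copy()
    if not config.noise_before_elimination:
        x, y = _noise(x, y)
    return SimulatedDataset(x=x, y=y, kept_x=kept_x, kept_y=kept_y, correlated=correlated)


def pair_statistics(ds: SimulatedDataset):
    """Masked Pearson r, support size and Fisher score per pair.

    Returns ``(n_support, r, I, testable)``; r and I are NaN where the pair
    is untestable (support < 4 or a constant gene on the support).
    """
    m = ds.kept_x & ds.kept_y
    n_s = m.sum(axis=1).astype(float)
    xm = np.where(m, ds.x, 0.0)
    ym = np.where(m, ds.y, 0.0)
    sx, sy = xm.sum(1), ym.sum(1)
    sxx, syy, sxy = (xm * xm).sum(1), (ym * ym).sum(1), (xm * ym).sum(1)
    vx = n_s * sxx - sx * sx
    vy = n_s * syy - sy * sy
    testable = (n_s >= MIN_SUPPORT) & (vx > 0) & (vy > 0)
    r = np.full(ds.x.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        r[testable] = (n_s * sxy - sx * sy)[testable] / np.sqrt((vx * vy)[testable])
    np.clip(r, -1.0, 1.0, out=r)
    I = np.full_like(r, np.nan)
    if testable.any():
        I[testable] = fisher_interaction(r[testable], n_s[testable])
    return n_s.astype(int), r, I, testable


def score_dataset(
    ds: SimulatedDataset,
    config: SimulationConfig,
    z_cut: float | None = None,
    elapsed: float = 0.0,
) -> SimulationReport:
    """Call significance per pair and tally the confusion matrix.

    Default rule: two-sided normal p-value, Bonferroni over the testable
    pairs at ``config.alpha``.  With ``z_cut`` given, a pair is called when
    |I| > z_cut instead (the calibrated-operating-point rule).
    """
    n_s, r, I, testable = pair_statistics(ds)
    m = int(testable.sum())
    if m == 0:
        raise ValidationError("all pairs untestable (support < 4 everywhere)")
    if z_cut is None:
        p = intra_state_pvalue(np.where(testable, I, 0.0))
        called = testable & (p * m < config.alpha)
        rule = "bonferroni"
    else:
        called = testable & (np.abs(I) > z_cut)
        rule = "z_cut"
    corr = ds.correlated
    tp = int(np.count_nonzero(called & corr))
    fp = int(np.count_nonzero(called & ~corr))
    fn = int(np.count_nonzero(testable & corr & ~called))
    tn = int(np.count_nonzero(testable & ~corr & ~called))
    return SimulationReport(
        config=config,
        rule=rule,
        z_cut=z_cut,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        n_untestable=int(np.count_nonzero(~testable)),
        n_untestable_correlated=int(np.count_nonzero(~testable & corr)),
        elapsed_seconds=elapsed,
    )


def run_scenario(config: SimulationConfig, z_cut: float | None = None) -> SimulationReport:
    """Generate and score one scenario (bit-reproducible from config.seed)."""
    t0 = time.perf_counter()
    ds = simulate_dataset(config)
    report = score_dataset(ds, config, z_cut=z_cut)
    return replace(report, elapsed_seconds=time.perf_counter() - t0)


def run_scenario_reps(
    config: SimulationConfig, z_cut: float | None = None
) -> list[SimulationReport]:
    """Run ``config.n_reps`` replicates with seeds seed, seed+1, ..."""
    return [
        run_scenario(replace(config, seed=config.seed + rep, n_reps=1), z_cut=z_cut)
        for rep in range(config.n_reps)
    ]


# ---------------------------------------------------------------------------
# Operating-point calibration
# ---------------------------------------------------------------------------


def calibrate_threshold(
    config: SimulationConfig, target_specificity: float = 0.85
) -> float:
    """Per-test |I| threshold realizing a requested specificity on null pairs.

    Simulates the scenario and returns the ``target_specificity`` quantile of
    |I| over the testable independent pairs — the per-test cut at which a
    fraction ``target_specificity`` of nulls is (correctly) not called.
    """
    if not 0 < target_specificity < 1:
        raise ValidationError("target_specificity must be in (0, 1)")
    ds = simulate_dataset(config)
    _, _, I, testable = pair_statistics(ds)
    null_scores = np.abs(I[testable & ~ds.correlated])
    if null_scores.size == 0:
        raise ValidationError("no testable null pairs to calibrate on")
    return float(np.quantile(null_scores, target_specificity))


def calibration_sweep(
    config: SimulationConfig, thresholds: Iterable[float] | None = None
) -> pd.DataFrame:
    """Sensitivity/specificity/accuracy across a grid of per-test thresholds.

    The default grid spans |I| cuts from 0.5 to the Bonferroni cut implied by
    ``config`` (two-sided alpha / n_pairs), exposing the whole operating
    curve of the scenario.
    """
    if thresholds is None:
        z_bonf = stats.norm.isf(config.alpha / config.n_pairs / 2.0)
        thresholds = np.round(np.linspace(0.5, z_bonf, 25), 4)
    ds = simulate_dataset(config)
    rows = []
    for z in thresholds:
        rep = score_dataset(ds, config, z_cut=float(z))
        rows.append(
            {
                "z_cut": float(z),
                "per_test_alpha": float(2 * stats.norm.sf(z)),
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "accuracy": rep.accuracy,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scenario sweeps
# ---------------------------------------------------------------------------


def sweep(
    configs: Iterable[SimulationConfig], z_cut: float | None = None
) -> pd.DataFrame:
    """Run a grid of scenarios; one row per scenario (NaN metrics where all
    pairs are untestable, the table's dash cells)."""
    rows = []
    for cfg in configs:
        try:
            reps = run_scenario_reps(cfg, z_cut=z_cut)
        except ValidationError:
            row = cfg.__dict__ | {
                "rule": "z_cut" if z_cut is not None else "bonferroni",
                "z_cut": z_cut,
                "accuracy": np.nan,
                "sensitivity": np.nan,
                "specificity": np.nan,
                "n_untestable": cfg.n_pairs,
                "elapsed_seconds": 0.0,
            }
            if cfg.n_reps > 1:
                row |= {
                    "accuracy_sd": np.nan,
                    "sensitivity_sd": np.nan,
                    "specificity_sd": np.nan,
                }
            rows.append(row)
            continue
        row = cfg.__dict__ | {
            "rule": reps[0].rule,
            "z_cut": z_cut,
            "accuracy": float(np.mean([r.accuracy for r in reps])),
            "sensitivity": float(np.mean([r.sensitivity for r in reps])),
            "specificity": float(np.mean([r.specificity for r in reps])),
            "n_untestable": int(np.mean([r.n_untestable for r in reps])),
            "elapsed_seconds": float(np.sum([r.elapsed_seconds for r in reps])),
        }
        if cfg.n_reps > 1:
            row |= {
                "accuracy_sd": float(np.std([r.accuracy for r in reps], ddof=1)),
                "sensitivity_sd": float(np.std([r.sensitivity for r in reps], ddof=1)),
                "specificity_sd": float(np.std([r.specificity for r in reps], ddof=1)),
            }
        rows.append(row)
    if not rows:
        raise ValidationError("empty scenario grid")
    return pd.DataFrame(rows)


def grid_configs(base: SimulationConfig, **axes) -> list[SimulationConfig]:
    """Cartesian product of parameter axes over a base config.

    ``grid_configs(base, K=[10, 20], tau=[0, 0.25])`` yields 4 configs.
    """
    configs = [base]
    for name, values in axes.items():
        configs = [replace(c, **{name: v}) for c in configs for v in values]
    return configs


def sweep_table(df: pd.DataFrame, metric: str, dash: str = "-") -> pd.DataFrame:
    """Pivot a K x tau sweep into a per-metric table with dashes for
    untestable scenarios."""
    table = df.pivot_table(index="K", columns="tau", values=metric, dropna=False)
    return table.map(lambda v: dash if pd.isna(v) else f"{v:.2f}")
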