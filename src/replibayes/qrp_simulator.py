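"""Generative models of questionable research practices (QRPs).

Three mechanisms that inflate false-positive rates and published effect
sizes are modelled:

* optional stopping — repeatedly testing accumulating data and stopping the
  moment p < α;
* publication bias (the file drawer) — significant results are always
  written up, non-significant ones only with some probability;
* HARKing — hypothesising after the results are known, operationalised as
  sign-aligning every effect estimate with the post-hoc prediction, so
  published effect sizes are never negative.

Observations are unit-variance normal and tests are standard t-tests with
closed-form p-values; everything is vectorised over simulated studies and
bit-reproducible under a fixed seed.  Common-random-number comparisons
(shared seed across peeking schedules) make monotonicity checks sharp at
desk scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OptionalStoppingDesign",
    "PublicationFilter",
    "QRPWorldConfig",
    "SimulationResult",
    "simulate_optional_stopping",
    "apply_publication_bias",
    "apply_harking",
    "simulate_publication_record",
]


@dataclass(frozen=True)
class OptionalStoppingDesign:
    """A peeking schedule for sequential significance testing.

    Peeks happen at per-group sizes ``n_min, n_min+step, ..., n_max``.  With
    ``n_min == n_max`` there is a single look and the procedure is an
    ordinary fixed-n test.  ``true_effect`` is the standardized mean
    difference δ (0 for a null effect).
    """

    n_min: int = 10
    n_max: int = 50
    step: int = 1
    alpha: float = 0.05
    test: Literal["one_sample", "two_sample"] = "two_sample"
    true_effect: float = 0.0
    n_sims: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.n_min <= self.n_max):
            raise ValueError("need 1 <= n_min <= n_max")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_sims < 1:
            raise ValueError("n_sims must be positive")
        if self.n_min < 2:
            raise ValueError("the t-test needs at least 2 observations per group")

    @property
    def peeks(self) -> np.ndarray:
        return np.arange(self.n_min, self.n_max + 1, self.step)


@dataclass(frozen=True)
class PublicationFilter:
    """Selective-reporting rule: keep significant results, drop others at random."""

    prob_report_nonsignificant: float = 0.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob_report_nonsignificant <= 1.0:
            raise ValueError("retention probability must lie in [0, 1]")


@dataclass(frozen=True)
class QRPWorldConfig:
    """How one lab produces candidate internal studies for one effect."""

    n_candidate_studies: int = 3
    optional_stopping: OptionalStoppingDesign | None = field(
        default_factory=OptionalStoppingDesign
    )
    publication_filter: PublicationFilter = field(default_factory=PublicationFilter)
    harking: bool = True
    n_per_study: int = 25  #: per-group size when optional stopping is off
    true_effect: float = 0.0
    alpha: float = 0.05


@dataclass
class SimulationResult:
    """Outputs of a QRP simulation.

    ``false_positive_rate`` is the fraction of simulated studies that ended
    significant; for a non-null ``true_effect`` it is the (QRP-inflated)
    power rather than a false-positive rate.
    """

    false_positive_rate: float
    mean_published_effect: float | None
    stop_n: np.ndarray
    effects: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    internal_replication_counts: np.ndarray | None
    n_sims: int
    seed: int | None
    design: dict

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("stop_n", "effects", "p_values", "significant",
                  "internal_replication_counts"):
            if d[k] is not None:
                d[k] = np.asarray(d[k]).tolist()
        return d


def _sequential_t(
    rng: np.random.Generator,
    design: OptionalStoppingDesign,
    effects: np.ndarray | None = None,
):
    """Vectorised sequential t-testing over ``n_sims`` studies.

    Returns (stop_n, p_at_stop, d_at_stop, significant).  Non-stopping
    studies report their final (n_max) test.  ``effects`` optionally gives a
    per-study δ overriding ``design.true_effect``.
    """
    n_sims, n_max = design.n_sims, design.n_max
    delta = (
        np.full(n_sims, design.true_effect)
        if effects is None
        else np.asarray(effects, dtype=float)
    )
    if delta.shape != (n_sims,):
        raise ValueError("effects must have length n_sims")

    if design.test == "one_sample":
        x = rng.standard_normal((n_sims, n_max)) + delta[:, None]
        groups = (x,)
    else:
        x = rng.standard_normal((n_sims, n_max)) + delta[:, None]
        y = rng.standard_normal((n_sims, n_max))
        groups = (x, y)

    cums = [g.cumsum(axis=1) for g in groups]
    cumsq = [(g**2).cumsum(axis=1) for g in groups]

    stop_n = np.full(n_sims, n_max)
    p_stop = np.full(n_sims, np.nan)
    d_stop = np.full(n_sims, np.nan)
    stopped = np.zeros(n_sims, dtype=bool)

    for n in design.peeks:
        k = n - 1
        means = [c[:, k] / n for c in cums]
        # unbiased variances from the running sums
        variances = [
            np.maximum((cq[:, k] - n * m**2) / (n - 1), 1e-300)
            for cq, m in zip(cumsq, means)
        ]
        if design.test == "one_sample":
            se = np.sqrt(variances[0] / n)
            t = means[0] / se
            df = n - 1
            d = means[0] / np.sqrt(variances[0])
        else:
            sp2 = (variances[0] + variances[1]) / 2.0
            t = (means[0] - means[1]) / np.sqrt(sp2 * 2.0 / n)
            df = 2 * n - 2
            d = (means[0] - means[1]) / np.sqrt(sp2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        hit = (~stopped) & (p < design.alpha)
        final = (~stopped) & (n == design.peeks[-1])
        for mask, sig in ((hit, True), (final & ~hit, False)):
            stop_n[mask] = n
            p_stop[mask] = p[mask]
            d_stop[mask] = d[mask]
        stopped |= hit
    return stop_n, p_stop, d_stop, stopped


def simulate_optional_stopping(design: OptionalStoppingDesign) -> SimulationResult:
    """Simulate 'sampling until significant' and measure its consequences.

    Each simulated study accumulates observations, tests at every peek and
    stops at the first p < α; studies that never cross the threshold report
    their final test at ``n_max``.
    """
    rng = np.random.default_rng(design.seed)
    stop_n, p, d, sig = _sequential_t(rng, design)
    return SimulationResult(
        false_positive_rate=float(np.mean(sig)),
        mean_published_effect=None,
        stop_n=stop_n,
        effects=d,
        p_values=p,
        significant=sig,
        internal_replication_counts=None,
        n_sims=design.n_sims,
        seed=design.seed,
        design=dataclasses.asdict(design),
    )


def apply_publication_bias(
    p_values: Sequence[float],
    effects: Sequence[float],
    filt: PublicationFilter,
    seed: int | None = None,
) -> dict:
    """Apply the file-drawer rule to a collection of study results.

    Significant results (p < α) are always retained; the rest survive with
    probability ``prob_report_nonsignificant``.  Returns the published
    subset together with the retention mask.
    """
    p = np.asarray(p_values, dtype=float)
    e = np.asarray(effects, dtype=float)
    rng = np.random.default_rng(seed)
    sig = p < filt.alpha
    keep = sig | (rng.uniform(size=p.shape) < filt.prob_report_nonsignificant)
    return {
        "published_p_values": p[keep],
        "published_effects": e[keep],
        "mask": keep,
        "n_published": int(keep.sum()),
    }


def apply_harking(effect_estimates: Sequence[float]) -> np.ndarray:
    """Sign-align effect estimates with the post-hoc hypothesis.

    Every estimate is reported as supporting the (adjusted) prediction, so
    the output is the elementwise absolute value, order preserved.
    """
    return np.abs(np.asarray(effect_estimates, dtype=float))


def simulate_publication_record(
    world: QRPWorldConfig,
    n_effects: int,
    seed: int | None = None,
    effects: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate each effect's lab running candidate internal studies.

    For every one of ``n_effects`` effects the lab runs
    ``world.n_candidate_studies`` studies under the enabled QRPs and
    publishes them through the publication filter.  An effect counts as
    internally replicated when at least two published significant studies
    exist; ``internal_replication_count`` is the number of published
    significant studies beyond the first.

    ``effects`` optionally supplies a per-effect true δ (default: the
    world's shared ``true_effect``).
    """
    rng = np.random.default_rng(seed)
    k = world.n_candidate_studies
    total = n_effects * k
    delta = (
        np.full(n_effects, world.true_effect)
        if effects is None
        else np.asarray(effects, dtype=float)
    )
    per_study_delta = np.repeat(delta, k)

    if world.optional_stopping is not None:
        design = dataclasses.replace(
            world.optional_stopping, n_sims=total, alpha=world.alpha
        )
        stop_n, p, d, sig = _sequential_t(rng, design, effects=per_study_delta)
    else:
        n = world.n_per_study
        design = OptionalStoppingDesign(
            n_min=n, n_max=n, alpha=world.alpha, test="two_sample", n_sims=total
        )
        stop_n, p, d, sig = _sequential_t(rng, design, effects=per_study_delta)

    if world.harking:
        d = apply_harking(d)

    keep = sig | (
        rng.uniform(size=total) < world.publication_filter.prob_report_nonsignificant
    )

    sig_m = sig.reshape(n_effects, k)
    keep_m = keep.reshape(n_effects, k)
    d_m = d.reshape(n_effects, k)
    pub_sig = (sig_m & keep_m).sum(axis=1)
    n_pub = keep_m.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_pub = np.where(
            n_pub > 0, np.nansum(np.where(keep_m, d_m, 0.0), axis=1) / np.maximum(n_pub, 1), np.nan
        )

    return pd.DataFrame(
        {
            "effect_id": np.arange(n_effects),
            "true_effect": delta,
            "is_null": delta == 0.0,
            "n_candidates": k,
            "n_published": n_pub,
            "n_published_significant": pub_sig,
            "internal_replication_count": np.maximum(pub_sig - 1, 0),
            "internally_replicated": pub_sig >= 2,
            "mean_published_effect": mean_pub,
        }
    )
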