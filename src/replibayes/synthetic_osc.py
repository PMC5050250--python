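"""Synthetic reproducibility-project-style datasets under two world models.

The generator produces study tables with the same schema as the real
reproducibility dataset, under two competing generative accounts:

* ``qrp_world`` — original effect sizes and significance are inflated by
  QRPs (optional stopping, publication bias, HARKing), and internal
  conceptual replications are manufactured by the same practices.  The
  internal-replication channel is simulated at a null effect, independent of
  the study's latent true effect, so internal replication carries *no*
  information about independent replication success: the world is exactly
  null for the primary comparison.

* ``moderator_world`` — identical, except that independent replications of
  internally replicated effects lose less of the latent effect: the
  replication's effect is attenuated by ``base_attenuation × (1 −
  coupling)`` instead of ``base_attenuation``.  With ``coupling = 0`` the
  two worlds coincide draw for draw.

Latent effects live on the correlation scale and are converted to
standardized mean differences (d = 2r/√(1−r²) for equal groups) for the
study simulators.  Independent replications are run cleanly (no QRPs) with
per-group sizes chosen to hit a target power (default .92) for the
*claimed* original effect size, mirroring how replication teams power their
studies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from . import qrp_simulator as qrp
from .study_records import StudyRecord, StudyTable

__all__ = [
    "WorldConfig",
    "generate_dataset",
    "world_discrimination_check",
    "r_to_d",
    "d_to_r",
    "two_sample_power",
    "n_for_power",
]


def r_to_d(r):
    """Correlation to standardized mean difference (equal group sizes)."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / np.sqrt(1.0 - r**2)


def d_to_r(d):
    """Standardized mean difference to correlation (equal group sizes)."""
    d = np.asarray(d, dtype=float)
    return d / np.sqrt(d**2 + 4.0)


def two_sample_power(d, n_per_group, alpha: float = 0.05):
    """Power of the two-sided two-sample t-test at per-group size n."""
    d = np.asarray(d, dtype=float)
    n = np.asarray(n_per_group, dtype=float)
    df = 2 * n - 2
    ncp = np.abs(d) * np.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    with np.errstate(all="ignore"):
        p = stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
        # scipy's noncentral t loses accuracy at large noncentrality;
        # fall back to the asymptotic normal form there
        approx = stats.norm.sf(tcrit - ncp) + stats.norm.cdf(-tcrit - ncp)
    p = np.where(np.isfinite(p), p, approx)
    return np.clip(p, 0.0, 1.0)


def n_for_power(
    d, target: float = 0.92, alpha: float = 0.05, n_max: int = 3000
) -> np.ndarray:
    """Smallest per-group n reaching the target power, by vectorised bisection."""
    d = np.atleast_1d(np.asarray(d, dtype=float))
    lo = np.full(d.shape, 2.0)
    hi = np.full(d.shape, float(n_max))
    for _ in range(30):
        mid = np.floor((lo + hi) / 2.0)
        ok = two_sample_power(d, mid, alpha) >= target
        hi = np.where(ok, mid, hi)
        lo = np.where(ok, lo, mid + 1)
    return hi.astype(int)


@dataclass(frozen=True)
class WorldConfig:
    """Study-generation settings shared by the two world models."""

    world: Literal["qrp_world", "moderator_world"] = "qrp_world"
    n_studies: int = 100
    fraction_internal: float = 0.44
    exact_margins: bool = True
    null_fraction: float = 0.45
    effect_loc: float = 0.30  #: latent correlation, truncated normal location
    effect_scale: float = 0.10
    target_power: float = 0.92
    rep_alpha: float = 0.05
    rep_n_max: int = 3000
    base_attenuation: float = 0.5
    coupling: float = 0.0  #: moderator_world only; 0 reduces to qrp_world
    p_cognitive: float = 0.42
    p_main_effect: float = 0.57
    p_power_analysis: float = 0.02
    n_missing_replication: tuple[int, int] = (2, 2)  #: (replicated, unreplicated)
    stopping: qrp.OptionalStoppingDesign = field(
        default_factory=qrp.OptionalStoppingDesign
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("fraction_internal", "null_fraction", "coupling",
                     "p_cognitive", "p_main_effect", "p_power_analysis",
                     "target_power", "base_attenuation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.fraction_internal >= 1.0:
            raise ValueError("fraction_internal must be < 1")
        if self.world == "qrp_world" and self.coupling != 0.0:
            raise ValueError("qrp_world requires coupling = 0")
        if self.n_studies < 1:
            raise ValueError("n_studies must be positive")
        # feasibility: the smallest claimed effect must reach the power target
        floor_power = float(
            two_sample_power(_R_FLOOR_D, self.rep_n_max, self.rep_alpha)
        )
        if floor_power < self.target_power:
            raise ValueError(
                f"power target {self.target_power} unreachable at rep_n_max="
                f"{self.rep_n_max} (max attainable {floor_power:.3f})"
            )


#: claimed original correlations are floored here when powering replications,
#: so the required sample size stays finite
_R_FLOOR = 0.05
_R_FLOOR_D = float(r_to_d(_R_FLOOR))

_CALIBRATION_SEED = 987_654_321
_calibration_cache: dict = {}


def _candidate_significance_rate(design: qrp.OptionalStoppingDesign) -> float:
    """Per-candidate significance rate of the stopping design at δ = 0.

    Estimated once per design by simulation with a fixed internal seed, so
    the internal-replication calibration is deterministic.
    """
    key = dataclasses.replace(design, n_sims=1, seed=None)
    if key not in _calibration_cache:
        probe = dataclasses.replace(
            design, n_sims=20_000, true_effect=0.0, seed=_CALIBRATION_SEED
        )
        _calibration_cache[key] = qrp.simulate_optional_stopping(
            probe
        ).false_positive_rate
    return _calibration_cache[key]


def _noncentral_t(rng: np.random.Generator, df, ncp) -> np.ndarray:
    """Draw noncentral-t variates as (Z + ncp) / sqrt(χ²_df / df)."""
    df = np.asarray(df, dtype=float)
    z = rng.standard_normal(np.shape(ncp))
    v = rng.chisquare(df)
    return (z + ncp) / np.sqrt(v / df)


def generate_dataset(config: WorldConfig) -> StudyTable:
    """Generate a study table under the configured world model."""
    n = config.n_studies
    master = np.random.SeedSequence(config.seed)
    (s_lat, s_orig, s_int, s_rep, s_cov, s_miss) = (
        np.random.default_rng(c) for c in master.spawn(6)
    )

    # latent true effects on the correlation scale
    is_null = s_lat.uniform(size=n) < config.null_fraction
    rho = np.clip(
        config.effect_loc + config.effect_scale * s_lat.standard_normal(n),
        0.05,
        0.90,
    )
    rho[is_null] = 0.0
    d_true = r_to_d(rho)

    # original study: optional stopping, then HARKing of the estimate
    design = dataclasses.replace(config.stopping, n_sims=n)
    stop_n, p_orig, d_obs, _sig = qrp._sequential_t(s_orig, design, effects=d_true)
    d_claimed = qrp.apply_harking(d_obs)
    r_original = d_to_r(d_claimed)
    n_original = 2 * stop_n

    # Internal-replication channel: QRP-manufactured significance at a null
    # effect, independent of the study's latent truth — the defining feature
    # of qrp_world.  Each lab runs k_i ~ Poisson(λ) candidate internal
    # studies under the same stopping design; λ is solved in closed form so
    # that P(≥ 1 significant internal study) equals fraction_internal:
    # #significant ~ Poisson(λ·s), hence λ = −ln(1 − f)/s.
    s_rate = _candidate_significance_rate(config.stopping)
    lam = -np.log(1.0 - config.fraction_internal) / s_rate
    k_i = s_int.poisson(lam, size=n)
    total = int(k_i.sum())
    counts = np.zeros(n, dtype=int)
    if total:
        cand_design = dataclasses.replace(
            config.stopping, n_sims=total, true_effect=0.0
        )
        _, _, _, cand_sig = qrp._sequential_t(s_int, cand_design)
        owner = np.repeat(np.arange(n), k_i)
        counts = np.bincount(owner[cand_sig], minlength=n)
    if config.exact_margins:
        m = int(round(config.fraction_internal * n))
        chosen = s_int.choice(n, size=m, replace=False)
        pool = counts[counts > 0]
        new = np.zeros(n, dtype=int)
        for i in chosen:
            new[i] = counts[i] if counts[i] > 0 else (
                int(s_int.choice(pool)) if pool.size else 1
            )
        counts = new
    counts = np.minimum(counts, 6)
    internal = counts > 0

    # independent replication, run cleanly at the configured power
    attenuation = config.base_attenuation * (1.0 - config.coupling * internal)
    rho_rep = rho * (1.0 - attenuation)
    d_rep = r_to_d(rho_rep)
    d_power_basis = r_to_d(np.maximum(r_original, _R_FLOOR))
    n_rep = n_for_power(
        d_power_basis, config.target_power, config.rep_alpha, config.rep_n_max
    )
    power = two_sample_power(d_power_basis, n_rep, config.rep_alpha)
    df = 2 * n_rep - 2
    t_rep = _noncentral_t(s_rep, df, d_rep * np.sqrt(n_rep / 2.0))
    p_rep = 2.0 * stats.t.sf(np.abs(t_rep), df)
    r_rep = d_to_r(t_rep * np.sqrt(2.0 / n_rep))

    # covariates (independent of the replication machinery)
    discipline = np.where(
        s_cov.uniform(size=n) < config.p_cognitive, "cognitive", "social"
    )
    effect_type = np.where(
        s_cov.uniform(size=n) < config.p_main_effect, "main", "interaction"
    )
    surprisingness = np.clip(3.1 + 0.9 * s_cov.standard_normal(n), 1.0, 6.0)
    challenge = -0.05 + 0.8 * s_cov.standard_normal(n)
    power_analysis = s_cov.uniform(size=n) < config.p_power_analysis

    # missing replication outcomes, a fixed number per group
    missing = np.zeros(n, dtype=bool)
    for grp_mask, n_miss in zip(
        (internal, ~internal), config.n_missing_replication
    ):
        idx = np.flatnonzero(grp_mask)
        if n_miss > len(idx):
            raise ValueError("more missing outcomes requested than group members")
        if n_miss:
            missing[s_miss.choice(idx, size=n_miss, replace=False)] = True

    records = []
    for i in range(n):
        records.append(
            StudyRecord(
                study_id=f"S{i:04d}",
                internal_replication_count=int(counts[i]),
                discipline=str(discipline[i]),
                effect_type=str(effect_type[i]),
                p_original=float(np.clip(p_orig[i], 1e-300, 1.0)),
                r_original=float(r_original[i]),
                n_original=int(n_original[i]),
                p_replication=None if missing[i] else float(np.clip(p_rep[i], 1e-300, 1.0)),
                r_replication=None if missing[i] else float(r_rep[i]),
                replication_power=float(power[i]),
                surprisingness=float(surprisingness[i]),
                challenge=float(challenge[i]),
                power_analysis_present=bool(power_analysis[i]),
            )
        )
    return StudyTable(
        records=records,
        provenance=(
            f"synthetic {config.world} (n={n}, coupling={config.coupling}, "
            f"seed={config.seed})"
        ),
    )


def world_discrimination_check(
    qrp_config: WorldConfig,
    moderator_config: WorldConfig,
    seed: int | None = None,
    pipeline=None,
) -> dict:
    """Run the primary comparison in both worlds and report the Bayes factors.

    The two configs must share every parameter except the world label and
    the coupling strength; ``pipeline`` defaults to the package's own
    primary comparison.
    """
    a = dataclasses.asdict(qrp_config)
    b = dataclasses.asdict(moderator_config)
    for k in ("world", "coupling", "seed"):
        a.pop(k), b.pop(k)
    if a != b:
        raise ValueError("configs must differ only in world, coupling and seed")
    if pipeline is None:
        from .pipeline import run_primary_comparison

        def pipeline(table, seed):
            return run_primary_comparison(table, seed=seed, include_effect_sizes=False)

    out = {}
    for name, cfg in (("qrp_world", qrp_config), ("moderator_world", moderator_config)):
        table = generate_dataset(
            dataclasses.replace(cfg, seed=seed if cfg.seed is None else cfg.seed)
        )
        report = pipeline(table, seed)
        row = report.rows[0]
        out[name] = {
            "bf_plus0": row.bf.bf_plus0,
            "bf_0plus": row.bf.bf_0plus,
            "successes": row.group_summary["successes"],
            "totals": row.group_summary["totals"],
        }
    return out
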