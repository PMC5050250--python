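"""Orchestration of the replication-success analyses.

Builds the three report families:

* the primary comparison — independent replication success (replication
  p < .05) of internally replicated vs internally unreplicated effects,
  via the one-sided Gunel–Dickey Bayes factor and Beta-posterior estimation,
  plus effect-size-reduction comparisons (simple subtraction and Cohen's q)
  via the JZS Bayes factor and robust estimation;
* the predictor comparisons — nine reproducibility predictors contrasted
  between the two groups;
* the field subgroups — the primary comparison repeated within social and
  cognitive psychology.

Directional alternatives are encoded declaratively per variable.  For every
categorical variable the alternative asserts that the coded level's share is
larger in the internally replicated group; the coded levels (success, social,
interaction, power-analysis-present) follow the reference analysis's sign
conventions and can be overridden.  Positive posterior medians always mean
support for the moderator-style alternative.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contingency_bayes import (
    BayesFactorResult,
    ContingencyTable2x2,
    GunelDickeyConfig,
    PosteriorSummary,
    bf_one_sided,
    posterior_contrast,
)
from .group_difference_bayes import (
    DegenerateDataError,
    GroupSample,
    JZSConfig,
    RobustModelConfig,
    jzs_bf,
    robust_difference,
)
from .study_records import (
    DEFAULT_EXCLUSION_THRESHOLD,
    StudyTable,
    es_reduction_q,
    es_reduction_simple,
    log_sample_size,
    replication_success_flag,
)

__all__ = [
    "ComparisonReport",
    "ReportRow",
    "run_primary_comparison",
    "run_predictor_comparisons",
    "run_field_subgroups",
    "jeffreys_label",
    "build_success_table",
    "GROUP_LABELS",
]

GROUP_LABELS = ("internally replicated", "internally unreplicated")


@dataclass
class ReportRow:
    variable: str
    kind: str  # "categorical" | "continuous"
    group_summary: dict
    bf: BayesFactorResult | None
    posteriors: list[PosteriorSummary]
    label: str
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "kind": self.kind,
            "group_summary": self.group_summary,
            "bf": self.bf.to_dict() if self.bf else None,
            "posteriors": [p.to_dict() for p in self.posteriors],
            "label": self.label,
            "notes": self.notes,
        }


@dataclass
class ComparisonReport:
    title: str
    rows: list[ReportRow]
    meta: dict

    def to_dict(self) -> dict:
        return {
            "title": self.title,
            "meta": self.meta,
            "rows": [r.to_dict() for r in self.rows],
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        lines = [self.title, "=" * len(self.title)]
        for row in self.rows:
            lines.append("")
            lines.append(f"{row.variable}")
            gs = row.group_summary
            if row.kind == "categorical" and "successes" in gs:
                for lab, y, n in zip(gs["group_labels"], gs["successes"], gs["totals"]):
                    lines.append(f"  {lab}: {y} out of {n} ({100 * y / n:.0f}%)")
            elif "means" in gs:
                for lab, m, s, n in zip(
                    gs["group_labels"], gs["means"], gs["sds"], gs["n"]
                ):
                    lines.append(f"  {lab}: M = {m:.3f} (SD = {s:.3f}, n = {n})")
            if row.bf is not None:
                bf0p, bfp0 = row.bf.bf_0plus, row.bf.bf_plus0
                if bfp0 is not None and bfp0 >= 1:
                    lines.append(f"  BF+0 = {bfp0:.2f} ({row.label})")
                elif bf0p is not None:
                    lines.append(f"  BF0+ = {bf0p:.2f} ({row.label})")
                else:
                    lines.append(f"  BF10 = {row.bf.bf10:.2f} ({row.label})")
            for p in row.posteriors:
                lines.append(
                    f"  {p.estimand}: median {p.median:.2f} "
                    f"[{p.ci_low:.2f}; {p.ci_high:.2f}]"
                )
            for note in row.notes:
                lines.append(f"  note: {note}")
        return "\n".join(lines) + "\n"


def jeffreys_label(bf: float) -> str:
    """Jeffreys' interpretation band for a Bayes factor.

    The band is read off the evidential magnitude max(BF, 1/BF), so a BF
    below 1 is labelled for the complementary hypothesis.  Boundary values
    fall into the higher band; BF = 1 is labelled anecdotal.
    """
    if not bf > 0:
        raise ValueError(f"Bayes factor must be positive, got {bf}")
    mag = max(bf, 1.0 / bf)
    if mag < 3.0:
        return "anecdotal"
    if mag < 10.0:
        return "substantial"
    if mag < 30.0:
        return "strong"
    return "very strong"


def _label_with_side(bf: BayesFactorResult) -> str:
    if bf.bf_plus0 is None:
        band = jeffreys_label(bf.bf10)
        side = "alternative" if bf.bf10 >= 1 else "null"
    else:
        band = jeffreys_label(bf.bf_plus0)
        side = "alternative" if bf.bf_plus0 >= 1 else "null"
    return f"{band} evidence for the {side}"


def _child_seeds(seed: int | None, k: int) -> list[int]:
    """Deterministic per-analysis integer seeds below 2**31."""
    state = np.random.SeedSequence(seed).generate_state(k, dtype=np.uint32)
    return [int(s >> 1) for s in state]


# ---------------------------------------------------------------------------
# building blocks


def build_success_table(
    table: StudyTable, alpha: float = 0.05
) -> tuple[ContingencyTable2x2, dict]:
    """2×2 replication-success table by internal-replication group.

    Records with a missing replication p-value are excluded from the counts;
    the exclusion tally is returned alongside, never applied silently.
    """
    rep, unrep = table.split_by_internal_replication()
    counts, totals, excluded = [], [], []
    for grp in (rep, unrep):
        flags = [replication_success_flag(r, alpha) for r in grp]
        known = [f for f in flags if f is not None]
        counts.append(sum(known))
        totals.append(len(known))
        excluded.append(len(flags) - len(known))
    ct = ContingencyTable2x2(
        group_labels=GROUP_LABELS,
        successes=(counts[0], counts[1]),
        totals=(totals[0], totals[1]),
    )
    return ct, {"excluded_missing": excluded, "alpha": alpha}


def _categorical_row(
    variable: str,
    ct: ContingencyTable2x2,
    seed: int,
    n_samples: int,
    a: float,
    direction: str,
    estimands: Sequence[str],
    notes: list[str] | None = None,
) -> ReportRow:
    s_bf, s_lo, s_pd = _child_seeds(seed, 3)
    cfg = GunelDickeyConfig(
        prior_concentration=a,
        direction=direction,
        n_posterior_samples=n_samples,
        seed=s_bf,
        method="sample",
    )
    bf = bf_one_sided(ct, cfg)
    posteriors = []
    for est, s in zip(estimands, (s_lo, s_pd)):
        posteriors.append(
            posterior_contrast(ct, dataclasses.replace(cfg, seed=s), est)
        )
    return ReportRow(
        variable=variable,
        kind="categorical",
        group_summary={
            "group_labels": list(ct.group_labels),
            "successes": list(ct.successes),
            "totals": list(ct.totals),
            "proportions": [y / n for y, n in zip(ct.successes, ct.totals)],
        },
        bf=bf,
        posteriors=posteriors,
        label=_label_with_side(bf),
        notes=list(notes or []),
    )


def _continuous_row(
    variable: str,
    values_rep: np.ndarray,
    values_unrep: np.ndarray,
    seed: int,
    direction: str,
    robust_samples: int,
    notes: list[str] | None = None,
    bf_values: tuple[np.ndarray, np.ndarray] | None = None,
) -> ReportRow:
    """JZS BF plus robust estimation for one continuous predictor.

    ``direction`` names the group whose mean the alternative asserts larger;
    the estimand is signed so a positive median supports that alternative.
    ``bf_values`` optionally supplies transformed values for the Bayes
    factor (e.g. log sample sizes) while estimation stays on the raw scale.
    """
    notes = list(notes or [])
    if len(values_rep) < 2 or len(values_unrep) < 2:
        return ReportRow(
            variable=variable,
            kind="continuous",
            group_summary={
                "group_labels": list(GROUP_LABELS),
                "n": [len(values_rep), len(values_unrep)],
            },
            bf=None,
            posteriors=[],
            label="insufficient data",
            notes=notes + ["fewer than 2 observations in a group; no BF emitted"],
        )
    s_rb = _child_seeds(seed, 1)[0]
    gr = GroupSample(np.asarray(values_rep, float), GROUP_LABELS[0])
    gu = GroupSample(np.asarray(values_unrep, float), GROUP_LABELS[1])
    if bf_values is not None:
        bf_gr = GroupSample(np.asarray(bf_values[0], float), GROUP_LABELS[0])
        bf_gu = GroupSample(np.asarray(bf_values[1], float), GROUP_LABELS[1])
    else:
        bf_gr, bf_gu = gr, gu
    try:
        bf = jzs_bf(bf_gr, bf_gu, JZSConfig(side="directional", direction=direction))
    except DegenerateDataError:
        bf = None
        notes.append("zero pooled variance; no BF emitted")
    # estimand signed so that positive = support for the directional alternative
    first, second = (gr, gu) if direction == GROUP_LABELS[0] else (gu, gr)
    post = robust_difference(
        first,
        second,
        RobustModelConfig(n_samples=robust_samples, burn_in=1_000, seed=s_rb),
    )
    if not post.diagnostics.get("converged", True):
        notes.append(f"robust-model chain not converged (rhat={post.diagnostics['rhat']:.3f})")
    return ReportRow(
        variable=variable,
        kind="continuous",
        group_summary={
            "group_labels": list(GROUP_LABELS),
            "means": [float(np.mean(gr.values)), float(np.mean(gu.values))],
            "sds": [float(np.std(gr.values, ddof=1)), float(np.std(gu.values, ddof=1))],
            "n": [len(gr.values), len(gu.values)],
            "estimand_sign": f"{first.label} minus {second.label}",
        },
        bf=bf,
        posteriors=[post],
        label=_label_with_side(bf) if bf else "insufficient data",
        notes=notes,
    )


def _effect_size_rows(
    table: StudyTable, seed: int, robust_samples: int
) -> list[ReportRow]:
    rep, unrep = table.split_by_internal_replication()
    rows = []
    for name, fn in (
        ("effect size reduction (simple subtraction)", es_reduction_simple),
        ("effect size reduction (Cohen's q)", es_reduction_q),
    ):
        per_group = []
        for grp in (rep, unrep):
            vals = [
                fn(r.r_original, r.r_replication)
                for r in grp
                if r.r_replication is not None and abs(r.r_original) < 1
                and abs(r.r_replication) < 1
            ]
            per_group.append(np.asarray(vals))
        rows.append(
            _continuous_row(
                name,
                per_group[0],
                per_group[1],
                seed=seed + len(rows),
                # moderator account: reduction smaller when internally replicated
                direction=GROUP_LABELS[1],
                robust_samples=robust_samples,
                notes=["raw reductions are typically non-normal; "
                       "prefer the robust posterior over the BF"],
            )
        )
    return rows


# ---------------------------------------------------------------------------
# public analyses


def run_primary_comparison(
    table: StudyTable,
    seed: int | None = None,
    n_samples: int = 100_000,
    alpha: float = 0.05,
    prior_concentration: float = 1.0,
    include_effect_sizes: bool = True,
    robust_samples: int = 20_000,
    min_group: int = 1,
) -> ComparisonReport:
    """Contrast independent replication success between the two groups.

    The directional alternative asserts greater replication success for
    internally replicated effects; BF_0+ > 1 therefore favours the
    no-difference null.  Both the log-odds-ratio and proportion-difference
    posteriors are reported.
    """
    ct, info = build_success_table(table, alpha=alpha)
    if min(ct.totals) < min_group:
        raise ValueError("each group needs at least one usable replication outcome")
    seeds = _child_seeds(seed, 2)
    rows = [
        _categorical_row(
            "independent replications P < .05",
            ct,
            seed=seeds[0],
            n_samples=n_samples,
            a=prior_concentration,
            direction=GROUP_LABELS[0],
            estimands=("log_odds_ratio", "proportion_difference"),
            notes=[f"records without replication p excluded: "
                   f"{info['excluded_missing']}"],
        )
    ]
    if include_effect_sizes:
        rows.extend(_effect_size_rows(table, seeds[1], robust_samples))
    return ComparisonReport(
        title="Primary comparison: independent replication success",
        rows=rows,
        meta={
            "seed": seed,
            "n_samples": n_samples,
            "alpha": alpha,
            "prior_concentration": prior_concentration,
            "n_records": len(table),
        },
    )


#: declarative predictor table; each entry is
#: (variable name, kind, value accessor, direction group), where the
#: accessor returns the coded-level flag for categorical variables and the
#: raw value for continuous ones
def _predictor_specs():
    return [
        ("field of study", "categorical",
         lambda r: r.discipline == "social", GROUP_LABELS[0]),
        ("effect type", "categorical",
         lambda r: r.effect_type == "interaction", GROUP_LABELS[0]),
        ("formal power analysis present", "categorical",
         lambda r: r.power_analysis_present, GROUP_LABELS[0]),
        ("original study P-value", "continuous",
         lambda r: r.p_original, GROUP_LABELS[0]),
        ("original effect size", "continuous",
         lambda r: r.r_original, GROUP_LABELS[1]),
        ("independent replication power", "continuous",
         lambda r: r.replication_power, GROUP_LABELS[1]),
        ("surprisingness of original effect", "continuous",
         lambda r: r.surprisingness, GROUP_LABELS[0]),
        ("challenge of conducting replication", "continuous",
         lambda r: r.challenge, GROUP_LABELS[0]),
    ]


def run_predictor_comparisons(
    table: StudyTable,
    seed: int | None = None,
    n_samples: int = 100_000,
    prior_concentration: float = 1.0,
    robust_samples: int = 20_000,
    exclusion_threshold: int = DEFAULT_EXCLUSION_THRESHOLD,
) -> ComparisonReport:
    """Contrast the reproducibility predictors between the two groups.

    Categorical predictors get the contingency Bayes factor (the coded
    level's share asserted larger among internally replicated effects, per
    the reference sign conventions); continuous predictors get the JZS
    Bayes factor and robust estimation.  Original sample size is analysed on
    the natural-log scale with the large-N outlier exclusion applied to the
    Bayes factor.
    """
    # predictors are contrasted over the records that enter the replication-
    # success analysis, i.e. those with a usable replication outcome
    n_all = len(table)
    table = table.subset(lambda r: r.p_replication is not None)
    rep, unrep = table.split_by_internal_replication()
    specs = _predictor_specs()
    seeds = _child_seeds(seed, len(specs) + 1)
    rows: list[ReportRow] = []
    for (name, kind, accessor, direction), s in zip(specs, seeds):
        if kind == "categorical":
            vals = []
            for grp in (rep, unrep):
                flags = [accessor(r) for r in grp]
                vals.append((sum(flags), len(flags)))
            ct = ContingencyTable2x2(
                group_labels=GROUP_LABELS,
                successes=(vals[0][0], vals[1][0]),
                totals=(vals[0][1], vals[1][1]),
            )
            rows.append(
                _categorical_row(
                    name, ct, seed=s, n_samples=n_samples,
                    a=prior_concentration, direction=direction,
                    estimands=("proportion_difference", "log_odds_ratio"),
                    notes=["reference tables print the proportion-difference "
                           "median for predictor rows; both estimands reported"],
                )
            )
        else:
            per_group = []
            for grp in (rep, unrep):
                per_group.append(
                    np.asarray([accessor(r) for r in grp
                                if accessor(r) is not None], dtype=float)
                )
            rows.append(
                _continuous_row(
                    name, per_group[0], per_group[1], seed=s,
                    direction=direction, robust_samples=robust_samples,
                )
            )

    # sample size: BF on the log scale with the outlier excluded,
    # estimation on raw values
    ln = log_sample_size(table, exclusion_threshold)
    by_id = dict(zip(ln["study_id"], zip(ln["log_n"], ln["excluded"])))
    raw, logs = [], []
    n_excluded = 0
    for grp in (rep, unrep):
        raw.append(np.asarray([r.n_original for r in grp], dtype=float))
        kept = []
        for r in grp:
            log_n, excl = by_id[r.study_id]
            if excl:
                n_excluded += 1
            else:
                kept.append(log_n)
        logs.append(np.asarray(kept))
    rows.append(
        _continuous_row(
            "sample size of original study",
            raw[0],
            raw[1],
            seed=seeds[-1],
            direction=GROUP_LABELS[1],
            robust_samples=robust_samples,
            notes=[
                "BF computed on natural-log sample sizes "
                f"({n_excluded} outlier(s) >= {exclusion_threshold} excluded); "
                "estimation on raw values",
            ],
            bf_values=(logs[0], logs[1]),
        )
    )
    return ComparisonReport(
        title="Reproducibility predictor comparison",
        rows=rows,
        meta={
            "seed": seed,
            "n_samples": n_samples,
            "prior_concentration": prior_concentration,
            "n_records": n_all,
            "n_usable": len(table),
            "excluded_missing_replication": n_all - len(table),
            "exclusion_threshold": exclusion_threshold,
        },
    )


def run_field_subgroups(
    table: StudyTable,
    seed: int | None = None,
    n_samples: int = 100_000,
    prior_concentration: float = 1.0,
    robust_samples: int = 20_000,
) -> ComparisonReport:
    """Repeat the primary comparison within each field of study."""
    rows: list[ReportRow] = []
    seeds = _child_seeds(seed, 2)
    for disc, s in zip(("social", "cognitive"), seeds):
        sub = table.subset(lambda r, d=disc: r.discipline == d)
        rep, unrep = sub.split_by_internal_replication()
        totals = [
            sum(1 for r in grp if r.p_replication is not None)
            for grp in (rep, unrep)
        ]
        if min(totals) < 2:
            successes = [
                sum(1 for r in grp if replication_success_flag(r) is True)
                for grp in (rep, unrep)
            ]
            rows.append(
                ReportRow(
                    variable=f"{disc} psychology: independent replications P < .05",
                    kind="categorical",
                    group_summary={
                        "group_labels": list(GROUP_LABELS),
                        "successes": successes,
                        "totals": totals,
                    },
                    bf=None,
                    posteriors=[],
                    label="insufficient data",
                    notes=["fewer than 2 studies in a group; no BF emitted"],
                )
            )
            continue
        ct, info = build_success_table(sub)
        rows.append(
            _categorical_row(
                f"{disc} psychology: independent replications P < .05",
                ct,
                seed=s,
                n_samples=n_samples,
                a=prior_concentration,
                direction=GROUP_LABELS[0],
                estimands=("log_odds_ratio", "proportion_difference"),
                notes=[f"records without replication p excluded: "
                       f"{info['excluded_missing']}"],
            )
        )
        rows.extend(_effect_size_rows(sub, s + 1, robust_samples))
    return ComparisonReport(
        title="Field-of-study subgroups",
        rows=rows,
        meta={
            "seed": seed,
            "n_samples": n_samples,
            "prior_concentration": prior_concentration,
            "n_records": len(table),
        },
    )
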