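"""Packaged deterministic fixture table.

:func:`reference_margins_table` builds a synthetic 100-study table whose
categorical cross-tabulations match the published summary margins of the
reproducibility-project re-analysis this package operationalises:

* 44 internally replicated effects (20 once, 10 twice, 9 three times,
  5 four times), 56 unreplicated;
* 42 / 54 usable replication outcomes (two missing per group);
* replication success 12/42 vs 22/54;
* field of study 13 cognitive + 29 social vs 29 cognitive + 25 social,
  with per-field success counts 7/13, 5/29, 14/29, 8/25;
* formal power analysis present for 0/42 vs 2/54.

All continuous columns are synthetic filler chosen only to respect the
schema's ranges and to vary across rows; they carry no information and no
analysis of them is meaningful beyond exercising the code paths.  The
fixture is fully deterministic (no RNG) so tests built on it are exact.
"""

from __future__ import annotations

from .study_records import StudyRecord, StudyTable

__all__ = ["reference_margins_table"]

# (n_records, discipline, success flag or None for missing outcome)
_REPLICATED_STRATA = [
    (7, "cognitive", True),
    (6, "cognitive", False),
    (5, "social", True),
    (24, "social", False),
    (2, "social", None),
]
_UNREPLICATED_STRATA = [
    (14, "cognitive", True),
    (15, "cognitive", False),  # the two power-analysis studies sit here
    (8, "social", True),
    (17, "social", False),
    (2, "social", None),
]

# internal-replication counts for the 44 replicated effects
_INTERNAL_COUNTS = [1] * 20 + [2] * 10 + [3] * 9 + [4] * 5


def _make_record(i: int, internal_count: int, discipline: str,
                 success: bool | None, power_analysis: bool) -> StudyRecord:
    # filler varies through a permuted index so it stays balanced across the
    # group strata (which are laid out in index order)
    j = (i * 37 + 11) % 100
    r_original = 0.20 + 0.005 * (j % 40)
    if success is None:
        p_rep, r_rep = None, None
    elif success:
        p_rep = 0.001 + 0.0004 * (j % 100)
        r_rep = max(r_original - 0.10, 0.02)
    else:
        p_rep = 0.10 + 0.008 * (j % 100)
        r_rep = 0.05 + 0.001 * (j % 30)
    return StudyRecord(
        study_id=f"F{i:03d}",
        internal_replication_count=internal_count,
        discipline=discipline,
        effect_type="main" if i % 2 == 0 else "interaction",
        p_original=0.001 + 0.0005 * (j % 80),
        r_original=r_original,
        n_original=40 + (j % 60),
        p_replication=p_rep,
        r_replication=r_rep,
        replication_power=0.90 + 0.0005 * (j % 80),
        surprisingness=2.0 + 0.02 * (j % 100),
        challenge=-0.50 + 0.01 * (j % 100),
        power_analysis_present=power_analysis,
    )


def reference_margins_table() -> StudyTable:
    """Synthetic study table matching the published contingency margins."""
    records: list[StudyRecord] = []
    i = 0
    rep_counts = iter(_INTERNAL_COUNTS)
    for n, discipline, success in _REPLICATED_STRATA:
        for _ in range(n):
            records.append(
                _make_record(i, next(rep_counts), discipline, success, False)
            )
            i += 1
    power_assigned = 0
    for n, discipline, success in _UNREPLICATED_STRATA:
        for _ in range(n):
            give_power = (
                discipline == "cognitive" and success is False and power_assigned < 2
            )
            records.append(_make_record(i, 0, discipline, success, give_power))
            if give_power:
                power_assigned += 1
            i += 1
    assert len(records) == 100 and power_assigned == 2
    return StudyTable(
        records=records,
        provenance="synthetic reconstruction of published summary margins",
    )
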