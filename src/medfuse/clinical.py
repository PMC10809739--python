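"""Published clinical worked-example figures, embedded verbatim, plus the
arithmetic that reproduces (and audits) them.

The source study reports its clinical evaluation only as printed summary
numbers: a 3x3 preoperative-stage vs pathological-stage confusion matrix
with marginals, per-phase diagnostic rates for the fusion-based and the
traditional workflow, counts of effectively treated patients per phase,
and satisfaction percentages for staff and patients.  No patient-level
data exist, so these printed numbers are the fixtures; every derived
statistic (concordance, averages, differences, totals) is recomputed from
them at call time.

The printed table is internally inconsistent: its row totals and its
overall accuracy do not match the printed cell counts.  The fixtures
preserve the table exactly as printed and :func:`consistency_check`
surfaces the mismatches instead of silently correcting them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = [
    "StagingTable",
    "PhaseRates",
    "EffectiveCounts",
    "SatisfactionDistribution",
    "Discrepancy",
    "TABLE2",
    "NEW_METHOD_RATES",
    "TRADITIONAL_RATES",
    "NEW_METHOD_EFFECTIVE",
    "TRADITIONAL_EFFECTIVE",
    "STAFF_SATISFACTION",
    "PATIENT_SATISFACTION",
    "PRINTED_OVERALL_ACCURACY",
    "PRINTED_PHASE_ACCURACIES",
    "concordance_rate",
    "mean_rate",
    "rate_gap",
    "effective_totals",
    "consistency_check",
    "clinical_report",
]

STAGE_LABELS = ("phase_1_2", "phase_3", "phase_4")
SATISFACTION_LABELS = ("dissatisfied", "generally_satisfied", "satisfied", "other")


@dataclass(frozen=True)
class StagingTable:
    """Image-fusion stage (rows) vs pathological stage (columns) counts,
    with the marginals exactly as printed (not recomputed)."""

    matrix: tuple[tuple[int, int, int], ...]
    printed_row_totals: tuple[int, int, int]
    printed_col_totals: tuple[int, int, int]
    printed_grand_total: int

    def __post_init__(self) -> None:
        if len(self.matrix) != 3 or any(len(r) != 3 for r in self.matrix):
            raise ValueError("staging matrix must be 3x3")
        if any(c < 0 for row in self.matrix for c in row):
            raise ValueError("staging counts must be >= 0")

    @property
    def row_sums(self) -> tuple[int, ...]:
        return tuple(sum(row) for row in self.matrix)

    @property
    def col_sums(self) -> tuple[int, ...]:
        return tuple(sum(col) for col in zip(*self.matrix))

    @property
    def grand_sum(self) -> int:
        return sum(self.row_sums)

    @property
    def diagonal_sum(self) -> int:
        return sum(self.matrix[i][i] for i in range(3))


@dataclass(frozen=True)
class PhaseRates:
    """Percentages for disease phases 1-4 under one diagnostic workflow."""

    rates: tuple[float, float, float, float]
    label: str

    def __post_init__(self) -> None:
        if len(self.rates) != 4:
            raise ValueError("exactly 4 phase rates are required")
        if any(not 0 <= r <= 100 for r in self.rates):
            raise ValueError("rates must lie in [0, 100]")


@dataclass(frozen=True)
class EffectiveCounts:
    """Patients effectively helped per phase, out of a treatment group."""

    counts: tuple[int, int, int, int]
    group_size: int = 50
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.counts) != 4:
            raise ValueError("exactly 4 phase counts are required")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be >= 0")
        if self.group_size <= 0:
            raise ValueError("group_size must be positive")
        if sum(self.counts) > self.group_size:
            raise ValueError("counts cannot exceed the group size")


@dataclass(frozen=True)
class SatisfactionDistribution:
    """Satisfaction-category percentages for one respondent cohort."""

    percentages: tuple[float, float, float, float]  # ordered per SATISFACTION_LABELS
    cohort: str

    def __post_init__(self) -> None:
        if len(self.percentages) != 4:
            raise ValueError("exactly 4 satisfaction percentages are required")
        if any(not 0 <= p <= 100 for p in self.percentages):
            raise ValueError("percentages must lie in [0, 100]")

    @property
    def satisfied(self) -> float:
        return self.percentages[SATISFACTION_LABELS.index("satisfied")]


@dataclass(frozen=True)
class Discrepancy:
    """One printed value that disagrees with its recomputation."""

    name: str
    printed: float
    recomputed: float

    @property
    def difference(self) -> float:
        return self.recomputed - self.printed


# --- embedded printed figures -------------------------------------------------

TABLE2 = StagingTable(
    matrix=((11, 7, 0), (5, 38, 6), (0, 14, 19)),
    printed_row_totals=(23, 41, 36),
    printed_col_totals=(16, 59, 25),
    printed_grand_total=100,
)

#: Overall staging accuracy as printed; does not follow from the matrix.
PRINTED_OVERALL_ACCURACY = 69.5
#: Per-phase accuracies as printed; no reconstruction from the matrix exists.
PRINTED_PHASE_ACCURACIES = {"phase_1_2": 69.6, "phase_3": 69.5, "phase_4": 69.4}

NEW_METHOD_RATES = PhaseRates((56.0, 68.0, 79.0, 91.0), label="image fusion diagnosis")
TRADITIONAL_RATES = PhaseRates((47.0, 54.0, 71.0, 87.0), label="traditional diagnosis")

NEW_METHOD_EFFECTIVE = EffectiveCounts((27, 9, 4, 2), group_size=50, label="image fusion diagnosis")
TRADITIONAL_EFFECTIVE = EffectiveCounts((22, 11, 2, 1), group_size=50, label="traditional diagnosis")

STAFF_SATISFACTION = SatisfactionDistribution((1.01, 3.78, 95.12, 0.09), cohort="medical staff")
PATIENT_SATISFACTION = SatisfactionDistribution((3.71, 6.23, 87.12, 2.94), cohort="patients")


# --- recomputed arithmetic ----------------------------------------------------

def concordance_rate(table: StagingTable) -> float:
    """Diagonal fraction: image staging agreeing with pathological staging."""
    total = table.grand_sum
    if total == 0:
        raise ValueError("concordance rate is undefined for an empty table")
    return table.diagonal_sum / total


def mean_rate(rates: PhaseRates) -> float:
    """Arithmetic mean of the four phase percentages."""
    return sum(rates.rates) / 4.0


def rate_gap(a: PhaseRates, b: PhaseRates) -> float:
    """Mean-rate difference ``a - b`` in percentage points."""
    return mean_rate(a) - mean_rate(b)


def effective_totals(counts: EffectiveCounts) -> tuple[int, float]:
    """Total effectively treated patients and their percentage of the group."""
    total = sum(counts.counts)
    return total, 100.0 * total / counts.group_size


def consistency_check(table: StagingTable | None = None) -> list[Discrepancy]:
    """Audit printed summary values against their recomputation.

    Checks the staging table's marginals and grand total, the printed
    overall accuracy (for the embedded table only), and the printed
    rate/count summaries.  Returns one record per mismatch; a fully
    self-consistent table yields an empty list.
    """
    audit_embedded = table is None
    table = table if table is not None else TABLE2
    records: list[Discrepancy] = []

    for label, printed, computed in zip(
        STAGE_LABELS, table.printed_row_totals, table.row_sums
    ):
        if printed != computed:
            records.append(Discrepancy(f"table2_row_total_{label}", printed, computed))
    for label, printed, computed in zip(
        STAGE_LABELS, table.printed_col_totals, table.col_sums
    ):
        if printed != computed:
            records.append(Discrepancy(f"table2_col_total_{label}", printed, computed))
    if table.printed_grand_total != table.grand_sum:
        records.append(
            Discrepancy("table2_grand_total", table.printed_grand_total, table.grand_sum)
        )

    if audit_embedded:
        recomputed_acc = 100.0 * concordance_rate(table)
        if abs(recomputed_acc - PRINTED_OVERALL_ACCURACY) > 1e-9:
            records.append(
                Discrepancy("overall_accuracy_percent", PRINTED_OVERALL_ACCURACY, recomputed_acc)
            )
        # printed summary statistics that do recompute exactly
        printed_summaries = [
            ("mean_diagnostic_rate_new", 73.5, mean_rate(NEW_METHOD_RATES)),
            ("mean_diagnostic_rate_traditional", 64.75, mean_rate(TRADITIONAL_RATES)),
            ("diagnostic_rate_gap", 8.75, rate_gap(NEW_METHOD_RATES, TRADITIONAL_RATES)),
            ("effective_total_new", 42, effective_totals(NEW_METHOD_EFFECTIVE)[0]),
            ("effective_percent_new", 84.0, effective_totals(NEW_METHOD_EFFECTIVE)[1]),
            ("effective_total_traditional", 36, effective_totals(TRADITIONAL_EFFECTIVE)[0]),
            ("effective_percent_traditional", 72.0, effective_totals(TRADITIONAL_EFFECTIVE)[1]),
            (
                "satisfaction_gap_satisfied",
                8.0,
                STAFF_SATISFACTION.satisfied - PATIENT_SATISFACTION.satisfied,
            ),
        ]
        for name, printed, recomputed in printed_summaries:
            if abs(recomputed - printed) > 1e-9:
                records.append(Discrepancy(name, printed, recomputed))

    return records


def _report_payload() -> dict:
    new_total, new_pct = effective_totals(NEW_METHOD_EFFECTIVE)
    trad_total, trad_pct = effective_totals(TRADITIONAL_EFFECTIVE)
    return {
        "table2": {
            "matrix": [list(r) for r in TABLE2.matrix],
            "printed_row_totals": list(TABLE2.printed_row_totals),
            "printed_col_totals": list(TABLE2.printed_col_totals),
            "printed_grand_total": TABLE2.printed_grand_total,
            "recomputed_row_totals": list(TABLE2.row_sums),
            "recomputed_col_totals": list(TABLE2.col_sums),
            "recomputed_grand_total": TABLE2.grand_sum,
            "recomputed_concordance_percent": 100.0 * concordance_rate(TABLE2),
            "printed_overall_accuracy_percent": PRINTED_OVERALL_ACCURACY,
            "printed_phase_accuracies_percent": dict(PRINTED_PHASE_ACCURACIES),
        },
        "diagnostic_rates": {
            "new_method": list(NEW_METHOD_RATES.rates),
            "traditional": list(TRADITIONAL_RATES.rates),
            "mean_new": mean_rate(NEW_METHOD_RATES),
            "mean_traditional": mean_rate(TRADITIONAL_RATES),
            "gap": rate_gap(NEW_METHOD_RATES, TRADITIONAL_RATES),
        },
        "effective_counts": {
            "new_method": list(NEW_METHOD_EFFECTIVE.counts),
            "traditional": list(TRADITIONAL_EFFECTIVE.counts),
            "group_size": NEW_METHOD_EFFECTIVE.group_size,
            "new_total": new_total,
            "new_percent": new_pct,
            "traditional_total": trad_total,
            "traditional_percent": trad_pct,
            "percent_gap": new_pct - trad_pct,
        },
        "satisfaction": {
            "labels": list(SATISFACTION_LABELS),
            "staff": list(STAFF_SATISFACTION.percentages),
            "patients": list(PATIENT_SATISFACTION.percentages),
            "satisfied_gap": STAFF_SATISFACTION.satisfied - PATIENT_SATISFACTION.satisfied,
        },
        "discrepancies": [
            {
                "name": d.name,
                "printed": d.printed,
                "recomputed": d.recomputed,
                "difference": d.difference,
            }
            for d in consistency_check()
        ],
    }


def clinical_report(format: str = "json") -> str:
    """Deterministic document of all fixtures, recomputed statistics and
    discrepancies, as JSON or plain text."""
    payload = _report_payload()
    if format == "json":
        return json.dumps(payload, indent=2, sort_keys=True)
    if format == "text":
        lines = ["Clinical worked-example report", "=" * 31, ""]
        t = payload["table2"]
        lines.append("Staging table (image fusion rows x pathological columns):")
        for label, row, printed in zip(
            STAGE_LABELS, t["matrix"], t["printed_row_totals"]
        ):
            lines.append(
                f"  {label:>9}: {row}  printed row total {printed}, "
                f"recomputed {sum(row)}"
            )
        lines.append(
            f"  concordance: {t['recomputed_concordance_percent']:.1f}% recomputed "
            f"vs {t['printed_overall_accuracy_percent']}% printed"
        )
        d = payload["diagnostic_rates"]
        lines.append("")
        lines.append(
            f"Diagnostic rates: new {d['new_method']} (mean {d['mean_new']}), "
            f"traditional {d['traditional']} (mean {d['mean_traditional']}), "
            f"gap {d['gap']} points"
        )
        e = payload["effective_counts"]
        lines.append(
            f"Effective treatment: new {e['new_total']}/{e['group_size']} "
            f"({e['new_percent']}%), traditional {e['traditional_total']}/"
            f"{e['group_size']} ({e['traditional_percent']}%), "
            f"gap {e['percent_gap']} points"
        )
        s = payload["satisfaction"]
        lines.append(
            f"Satisfaction ('satisfied'): staff {s['staff'][2]}% vs patients "
            f"{s['patients'][2]}%, gap {s['satisfied_gap']} points"
        )
        lines.append("")
        lines.append(f"Discrepancies ({len(payload['discrepancies'])}):")
        for rec in payload["discrepancies"]:
            lines.append(
                f"  {rec['name']}: printed {rec['printed']}, "
                f"recomputed {rec['recomputed']} (diff {rec['difference']:+g})"
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {format!r}; use 'json' or 'text'")
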