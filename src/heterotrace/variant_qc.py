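"""Hard site filters and the genotype call-rate rule.

Each criterion is a removal condition: a record is removed iff any enabled
criterion fires. By default, thresholds are the printed ones: MQ < 15,
SOR > 4, QD < 20, FS > 60, MQRankSum < -10, ReadPosRankSum outside [-2, 2],
DP outside [6, 100] ("between" read as inclusive). A missing annotation
cannot be evaluated and passes its criterion unless ``strict`` is set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .core_io import VariantRecord, VariantTable


@dataclass
class FilterPolicy:
    mq_min: float | None = 15.0         # remove if MQ < mq_min
    sor_max: float | None = 4.0         # remove if SOR > sor_max
    qd_min: float | None = 20.0         # remove if QD < qd_min (as printed)
    fs_max: float | None = 60.0         # remove if FS > fs_max
    mq_rank_min: float | None = -10.0   # remove if MQRankSum < mq_rank_min
    read_pos_rank_abs: float | None = 2.0  # remove if |ReadPosRankSum| > this
    dp_min: float | None = 6.0          # remove if DP outside [dp_min, dp_max]
    dp_max: float | None = 100.0
    min_call_rate: float = 0.75
    strict: bool = False  # missing annotation fails instead of passing

    def __post_init__(self) -> None:
        if self.dp_min is not None and self.dp_max is not None:
            if not self.dp_min < self.dp_max:
                raise ValueError("dp_min must be < dp_max")
        if not 0.0 < self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in (0, 1]")

    def failing_criteria(self, rec: VariantRecord) -> list[str]:
        """Names of every removal criterion that fires for this record."""
        qc = rec.qc
        strict = self.strict
        failed: list[str] = []
        for key, enabled in (
            ("MQ", self.mq_min), ("SOR", self.sor_max), ("QD", self.qd_min),
            ("FS", self.fs_max), ("MQRankSum", self.mq_rank_min),
            ("ReadPosRankSum", self.read_pos_rank_abs), ("DP", self.dp_min),
        ):
            if enabled is None:
                continue
            v = qc.get(key)
            if v is None:
                if strict:
                    failed.append(key)
                continue
            if key == "MQ" and v < self.mq_min:
                failed.append(key)
            elif key == "SOR" and v > self.sor_max:
                failed.append(key)
            elif key == "QD" and v < self.qd_min:
                failed.append(key)
            elif key == "FS" and v > self.fs_max:
                failed.append(key)
            elif key == "MQRankSum" and v < self.mq_rank_min:
                failed.append(key)
            elif key == "ReadPosRankSum" and abs(v) > self.read_pos_rank_abs:
                failed.append(key)
            elif key == "DP" and self.dp_max is not None and not (
                self.dp_min <= v <= self.dp_max
            ):
                failed.append(key)
        return failed


def hard_filter(
    table: VariantTable, policy: FilterPolicy | None = None
) -> tuple[VariantTable, Counter]:
    """Apply the hard site filters; return survivors and a per-criterion
    removal tally (a record may fire several criteria, so the tally sum can
    exceed the number of records removed)."""
    policy = policy or FilterPolicy()
    tally: Counter = Counter()
    kept = []
    for rec in table.records:
        failed = policy.failing_criteria(rec)
        if failed:
            tally.update(failed)
        else:
            kept.append(rec)
    return VariantTable(table.samples, kept), tally


def call_rate_filter(table: VariantTable, min_rate: float = 0.75) -> VariantTable:
    """Keep records with at least ``min_rate`` of genotypes called
    (boundary inclusive)."""
    kept = [r for r in table.records if r.call_rate >= min_rate]
    return VariantTable(table.samples, kept)
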