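"""Binary appearance-pattern analysis.

Intensities are binarized (1 = observed with any positive intensity), per
condition presence counts are tallied over the paired design, and
condition-unique proteins are detected with a pooled two-proportion z-test.

The proportion test form — pooled-variance z statistic, two-sided normal
tail, no continuity correction — was fixed by requiring exact agreement
with independently published per-count p-values (9/10 vs 0/10 -> 5.23e-5,
6/10 -> 3.41e-3, 5/10 -> 9.82e-3, 4/10 -> 2.53e-2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from proteopair.io import IntensityMatrix, PairedDesign

__all__ = [
    "AppearanceMatrix",
    "ProportionTestResult",
    "UniqueProteinRecord",
    "binarize",
    "condition_presence_counts",
    "proportion_z_test",
    "detect_unique_proteins",
    "per_sample_protein_counts",
]

logger = logging.getLogger(__name__)


@dataclass
class AppearanceMatrix:
    """Binary observation patterns: 1 = positive intensity, 0 = absent."""

    protein_ids: list[str]
    sample_ids: list[str]
    bits: np.ndarray  # shape (n_proteins, n_samples), int8 in {0,1}

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("appearance bits must be 0 or 1")
        self.bits = self.bits.astype(np.int8)
        if self.bits.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise ValueError("bits shape does not match ids")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class ProportionTestResult:
    """Pooled two-proportion z-test outcome for counts k1/n1 vs k2/n2."""

    k1: int
    n1: int
    k2: int
    n2: int
    z: float
    p_value: float


@dataclass
class UniqueProteinRecord:
    """A protein observed only in one condition, above the presence floor."""

    protein_id: str
    condition: str
    n_present: int
    fraction: float
    p_value: float
    q_value: float = math.nan


def binarize(m: IntensityMatrix) -> AppearanceMatrix:
    """Map intensities to bits: 1 iff intensity > 0."""
    return AppearanceMatrix(
        protein_ids=list(m.protein_ids),
        sample_ids=list(m.sample_ids),
        bits=(m.values > 0).astype(np.int8),
    )


def condition_presence_counts(
    a: AppearanceMatrix, d: PairedDesign
) -> tuple[np.ndarray, np.ndarray]:
    """Per-protein counts of subjects observed in each condition.

    Returns (k_a, k_b), each of length n_proteins, where k_a[i] is the number
    of subjects whose condition-A sample has the protein.  Columns not in
    the design are ignored (with a logged warning).
    """
    missing = [s for s in d.all_samples() if s not in a.sample_ids]
    if missing:
        raise ValueError(f"design samples absent from matrix: {missing}")
    extra = set(a.sample_ids) - set(d.all_samples())
    if extra:
        logger.warning("ignoring %d matrix columns not in the design: %s",
                       len(extra), sorted(extra))
    col = {s: j for j, s in enumerate(a.sample_ids)}
    idx_a = [col[s] for s in d.samples_for(d.condition_a)]
    idx_b = [col[s] for s in d.samples_for(d.condition_b)]
    k_a = a.bits[:, idx_a].sum(axis=1)
    k_b = a.bits[:, idx_b].sum(axis=1)
    return np.asarray(k_a, dtype=int), np.asarray(k_b, dtype=int)


def proportion_z_test(k1: int, n1: int, k2: int, n2: int) -> ProportionTestResult:
    """Two-sided pooled two-proportion z-test, no continuity correction.

    z = (k1/n1 - k2/n2) / sqrt(phat (1-phat) (1/n1 + 1/n2)) with the pooled
    frequency phat = (k1+k2)/(n1+n2); p is the two-sided standard-normal
    tail.  If phat is 0 or 1 (both groups all-absent or all-present) the
    difference is identically zero: z = 0, p = 1.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n:
            raise ValueError(f"count k={k} outside [0, n={n}]")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ProportionTestResult(k1, n1, k2, n2, z=0.0, p_value=1.0)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return ProportionTestResult(k1, n1, k2, n2, z=z, p_value=min(p, 1.0))


def detect_unique_proteins(
    a: AppearanceMatrix, d: PairedDesign, min_fraction: float = 0.4
) -> list[UniqueProteinRecord]:
    """Detect condition-unique proteins.

    A protein is unique for condition X iff it is observed in at least
    ceil(min_fraction * n_subjects) subjects of X and in zero samples of the
    other condition.  Each record carries the proportion-test p-value
    against 0/n and a Benjamini-Hochberg q-value across all reported
    records.  Records are sorted by descending fraction then protein id.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    from proteopair.paired_de import benjamini_hochberg

    n = d.n_subjects
    k_min = math.ceil(min_fraction * n)
    k_a, k_b = condition_presence_counts(a, d)
    records: list[UniqueProteinRecord] = []
    for i, pid in enumerate(a.protein_ids):
        for cond, k_here, k_other in (
            (d.condition_a, int(k_a[i]), int(k_b[i])),
            (d.condition_b, int(k_b[i]), int(k_a[i])),
        ):
            if k_here >= k_min and k_other == 0:
                res = proportion_z_test(k_here, n, 0, n)
                records.append(
                    UniqueProteinRecord(
                        protein_id=pid,
                        condition=cond,
                        n_present=k_here,
                        fraction=k_here / n,
                        p_value=res.p_value,
                    )
                )
    records.sort(key=lambda r: (-r.fraction, r.protein_id))
    if records:
        qs = benjamini_hochberg([r.p_value for r in records])
        for r, q in zip(records, qs):
            r.q_value = q
    return records


def per_sample_protein_counts(a: AppearanceMatrix) -> dict[str, int]:
    """Number of observed proteins per sample (column sums of the bits)."""
    counts = a.bits.sum(axis=0)
    return {s: int(c) for s, c in zip(a.sample_ids, counts)}
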