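"""Seeded generator of paired proteome datasets with planted effects.

Emulates the statistical shape the analysis assumes: two conditions over a
modest subject panel, heavy zero-inflation via independent Bernoulli
detection, log-normal positive intensities, a planted set of
condition-unique proteins at defined presence fractions, and a block of
intensity-shifted proteins for the differential-expression and enrichment
stages.  Also builds a small deterministic appearance fixture whose
per-condition presence counts match a published two-table layout of
condition-unique proteins (9,5,4,4,4 of 10 in one condition; three at 6,
eight at 5 and seven at 4 of 10 in the other; zero opposite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from proteopair.appearance import AppearanceMatrix
from proteopair.io import GeneSetCollection, IntensityMatrix, PairedDesign

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_paired_proteome",
    "build_tables_fixture",
    "generate_annotation_sets",
    "TABLE_UNIQUE_A",
    "TABLE_UNIQUE_B",
]

# (accession, subjects-present of 10) for the two-condition unique fixture.
TABLE_UNIQUE_A: list[tuple[str, int]] = [
    ("Q16678", 9),  # Cytochrome P450 1B1
    ("O94788", 5),  # Retinal dehydrogenase 2
    ("P02812", 4),  # Basic salivary proline-rich protein 2
    ("Q13740", 4),  # CD166 antigen
    ("P08582", 4),  # Melanotransferrin
]
TABLE_UNIQUE_B: list[tuple[str, int]] = [
    ("P28330", 6),  # Long-chain specific acyl-CoA dehydrogenase
    ("Q96HY7", 6),  # Probable 2-oxoglutarate dehydrogenase E1 DHKTD1
    ("P04440", 6),  # HLA class II histocompatibility antigen DP beta 1
    ("P47712", 5),  # Cytosolic phospholipase A2
    ("Q8IWW8", 5),  # Hydroxyacid-oxoacid transhydrogenase
    ("Q10713", 5),  # Mitochondrial-processing peptidase subunit alpha
    ("Q6GTX8; Q6ISS4", 5),  # Leukocyte-associated Ig-like receptor 1
    ("Q13424", 5),  # Alpha-1-syntrophin
    ("Q5TFE4", 5),  # 5-nucleotidase domain-containing protein 1
    ("Q92552", 5),  # 28S ribosomal protein S27
    ("Q96GG9", 5),  # DCN1-like protein 1
    ("Q14008", 4),  # Cytoskeleton-associated protein 5
    ("Q6L8Q7", 4),  # 2,5-phosphodiesterase 12
    ("P10619", 4),  # Lysosomal protective protein
    ("P27918", 4),  # Properdin
    ("Q9BYT8", 4),  # Neurolysin
    ("O94925", 4),  # Glutaminase kidney isoform
    ("P06454", 4),  # Prothymosin alpha
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic paired proteome."""

    n_subjects: int = 10
    n_proteins: int = 2773
    condition_a: str = "orbital"
    condition_b: str = "abdominal"
    n_unique_a: int = 5
    n_unique_b: int = 18
    unique_fractions_a: tuple[float, ...] = (0.9, 0.5, 0.4, 0.4, 0.4)
    unique_fractions_b: tuple[float, ...] = (0.6,) * 3 + (0.5,) * 8 + (0.4,) * 7
    n_shifted: int = 20
    shift_effect: float = 8.0
    detection_prob: float = 0.7
    intensity_log_mean: float = 20.0  # log2 scale
    intensity_log_sd: float = 2.0
    n_decoy_sets: int = 10
    enriched_set_size: int = 10
    decoy_set_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_unique_a, self.n_unique_b, self.n_shifted) < 0:
            raise ValueError("planted counts must be >= 0")
        if self.n_unique_a + self.n_unique_b + self.n_shifted > self.n_proteins:
            raise ValueError("planted counts exceed n_proteins")
        if not 0 <= self.detection_prob <= 1:
            raise ValueError("detection_prob must lie in [0, 1]")
        for f in self.unique_fractions_a + self.unique_fractions_b:
            if not 0 < f <= 1:
                raise ValueError("presence fractions must lie in (0, 1]")


@dataclass
class GroundTruth:
    """Identities of the planted effects in a synthetic dataset."""

    unique_a: list[str] = field(default_factory=list)
    unique_b: list[str] = field(default_factory=list)
    shifted: list[str] = field(default_factory=list)
    enriched_sets: dict[str, list[str]] = field(default_factory=dict)

    @property
    def planted(self) -> list[str]:
        return self.unique_a + self.unique_b + self.shifted


def _design(n_subjects: int, cond_a: str, cond_b: str) -> PairedDesign:
    subjects = [f"S{i + 1:02d}" for i in range(n_subjects)]
    pairs = {
        s: {cond_a: f"{s}_{cond_a}", cond_b: f"{s}_{cond_b}"} for s in subjects
    }
    return PairedDesign(
        subjects=subjects, condition_a=cond_a, condition_b=cond_b, pairs=pairs
    )


def generate_paired_proteome(
    c: SyntheticConfig,
) -> tuple[IntensityMatrix, PairedDesign, GroundTruth]:
    """Generate a paired intensity matrix with planted effects.

    Protein layout: condition-A-unique proteins first, then
    condition-B-unique, then intensity-shifted, then background.  Background
    proteins are detected per sample independently with probability
    `detection_prob`; planted unique proteins appear in exactly
    round(fraction * n_subjects) randomly chosen subjects of their condition
    and nowhere in the other; shifted proteins are detected everywhere with
    condition-A intensities multiplied by `shift_effect`.  Positive
    intensities are log-normal (base 2).  Fully reproducible per seed.
    """
    rng = np.random.default_rng(c.seed)
    n, p = c.n_subjects, c.n_proteins
    d = _design(n, c.condition_a, c.condition_b)
    sample_ids = d.samples_for(c.condition_a) + d.samples_for(c.condition_b)
    protein_ids = [f"PROT{i:05d}" for i in range(p)]

    truth = GroundTruth(
        unique_a=protein_ids[: c.n_unique_a],
        unique_b=protein_ids[c.n_unique_a : c.n_unique_a + c.n_unique_b],
        shifted=protein_ids[
            c.n_unique_a + c.n_unique_b : c.n_unique_a + c.n_unique_b + c.n_shifted
        ],
    )

    bits = np.zeros((p, 2 * n), dtype=np.int8)
    a_cols = np.arange(n)
    b_cols = np.arange(n, 2 * n)

    row = 0
    for count, fractions, cols in (
        (c.n_unique_a, c.unique_fractions_a, a_cols),
        (c.n_unique_b, c.unique_fractions_b, b_cols),
    ):
        for j in range(count):
            f = fractions[j % len(fractions)]
            k = int(round(f * n))
            subj = rng.choice(n, size=k, replace=False)
            bits[row, cols[subj]] = 1
            row += 1
    bits[row : row + c.n_shifted, :] = 1
    row += c.n_shifted
    bits[row:, :] = rng.random((p - row, 2 * n)) < c.detection_prob

    log_int = rng.normal(c.intensity_log_mean, c.intensity_log_sd, size=(p, 2 * n))
    values = np.where(bits == 1, np.exp2(log_int), 0.0)
    shifted_rows = slice(c.n_unique_a + c.n_unique_b, c.n_unique_a + c.n_unique_b + c.n_shifted)
    values[shifted_rows, :n] *= c.shift_effect

    m = IntensityMatrix(protein_ids=protein_ids, sample_ids=sample_ids, values=values)
    return m, d, truth


def build_tables_fixture() -> tuple[AppearanceMatrix, PairedDesign]:
    """Deterministic 23-protein appearance fixture over 10 subjects.

    Presence counts follow the published two-table layout; presence is
    assigned to the lowest-index subjects (the proportion test depends only
    on counts, so the choice is immaterial).
    """
    n = 10
    d = _design(n, "orbital", "abdominal")
    sample_ids = d.samples_for("orbital") + d.samples_for("abdominal")
    protein_ids = [acc for acc, _ in TABLE_UNIQUE_A + TABLE_UNIQUE_B]
    bits = np.zeros((len(protein_ids), 2 * n), dtype=np.int8)
    for i, (_, k) in enumerate(TABLE_UNIQUE_A):
        bits[i, :k] = 1
    for i, (_, k) in enumerate(TABLE_UNIQUE_B, start=len(TABLE_UNIQUE_A)):
        bits[i, n : n + k] = 1
    return (
        AppearanceMatrix(protein_ids=protein_ids, sample_ids=sample_ids, bits=bits),
        d,
    )


def generate_annotation_sets(g: GroundTruth, c: SyntheticConfig) -> GeneSetCollection:
    """Build one planted enriched set plus decoy sets, GMT-writable.

    The planted set is drawn from the planted-effect proteins (which are
    genuinely top-ranked under the differential tests); decoys are disjoint
    random background proteins.  The planted membership is recorded in the
    ground truth under term id "PLANTED".
    """
    if not g.planted:
        raise ValueError("ground truth has no planted proteins to enrich")
    rng = np.random.default_rng(np.random.SeedSequence((c.seed, 0xA11)))
    size = min(c.enriched_set_size, len(g.planted))
    planted = sorted(rng.choice(g.planted, size=size, replace=False).tolist())
    background = [
        f"PROT{i:05d}"
        for i in range(c.n_unique_a + c.n_unique_b + c.n_shifted, c.n_proteins)
    ]
    sets: dict[str, tuple[str, list[str]]] = {
        "PLANTED": ("planted enriched set", planted)
    }
    for j in range(c.n_decoy_sets):
        members = sorted(
            rng.choice(background, size=min(c.decoy_set_size, len(background)),
                       replace=False).tolist()
        )
        sets[f"DECOY{j:02d}"] = (f"decoy set {j}", members)
    g.enriched_sets = {"PLANTED": planted}
    return GeneSetCollection(sets=sets)
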