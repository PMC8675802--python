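"""Embedded worked-example fixtures and a synthetic expression generator.

The fixture tables are the small worked examples used throughout the
documentation and test suite: a 5 x 6 raw microarray excerpt and its
normalized counterpart, two 4 x 4 pairwise interaction-strength matrices
(before and after threshold filtering), and a 2 x 9 pair of raw expression
rows used by the direction classifier's worked example.

The generator emulates log-scale microarray intensities (baseline around
7 with spread comparable to the fixture tables' 4-9 range) and plants
regulator -> target co-expression so the whole pipeline is testable
without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = ["SyntheticSpec", "fixture_tables", "generate", "generate_condition_pair"]

_SAMPLES6 = [f"Sample{i}" for i in range(1, 7)]
_GENES5 = [f"Gene{i}" for i in range(1, 6)]
_GENES4 = [f"Gene{i}" for i in range(1, 5)]

# 5 genes x 6 samples of raw microarray intensities.
_TABLE1 = [
    [5.27055, 5.07397, 5.20949, 5.25106, 5.38327, 5.13528],
    [7.41519, 7.11951, 8.54414, 7.73497, 7.70082, 8.04083],
    [5.04245, 5.01335, 5.15868, 4.58296, 5.15520, 4.58029],
    [5.89670, 5.82747, 6.10051, 5.71561, 6.25209, 5.96030],
    [4.68734, 4.62737, 4.71932, 4.77644, 4.63229, 4.29907],
]

# The same excerpt after per-gene max-min rescaling (printed to 4 dp).
_TABLE2 = [
    [0.6355, 0.0000, 0.4381, 0.5725, 1.0000, 0.1982],
    [0.2075, 0.0000, 1.0000, 0.4320, 0.4080, 0.6467],
    [0.7990, 0.7487, 1.0000, 0.0046, 0.9939, 0.0000],
    [0.3375, 0.2085, 0.7174, 0.0000, 1.0000, 0.4561],
    [0.8133, 0.6877, 0.8803, 1.0000, 0.6980, 0.0000],
]

# Pairwise interaction strengths after training, row gene's side of each
# pair; diagonal undefined.
_TABLE3 = [
    [np.nan, 0.765, 0.772, 0.698],
    [0.779, np.nan, 0.730, 0.721],
    [0.770, 0.733, np.nan, 0.700],
    [0.6695, 0.736, 0.682, np.nan],
]

# Same matrix as carried into the theta-filter walk-through (one cell,
# Gene3/Gene4, differs from the post-training table: 0.6843 vs 0.7; the
# filtering walk-through is only consistent with this version).
_TABLE4 = [
    [np.nan, 0.765, 0.772, 0.698],
    [0.779, np.nan, 0.730, 0.721],
    [0.770, 0.733, np.nan, 0.6843],
    [0.6695, 0.736, 0.682, np.nan],
]

# Raw expression rows for the direction classifier's worked example.
_TABLE5 = {
    "Gene1": [4.3078, 4.5863, 4.8488, 4.7809, 4.1483, 3.8997, 4.2633, 4.2199, 4.4515],
    "Gene3": [7.0182, 6.6068, 8.3893, 8.1416, 7.5879, 6.7963, 8.4705, 7.2029, 5.5523],
}


def fixture_tables() -> dict[str, pd.DataFrame]:
    """Fresh copies of the embedded worked-example tables.

    Keys: ``table1`` (5x6 raw), ``table2`` (5x6 normalized, 4 dp),
    ``table3`` / ``table4`` (4x4 strength matrices), ``table5`` (2x9 raw
    rows for Gene1 and Gene3).
    """
    return {
        "table1": pd.DataFrame(_TABLE1, index=_GENES5, columns=_SAMPLES6, dtype=float),
        "table2": pd.DataFrame(_TABLE2, index=_GENES5, columns=_SAMPLES6, dtype=float),
        "table3": pd.DataFrame(_TABLE3, index=_GENES4, columns=_GENES4, dtype=float),
        "table4": pd.DataFrame(_TABLE4, index=_GENES4, columns=_GENES4, dtype=float),
        "table5": pd.DataFrame(
            _TABLE5, index=[f"s{i}" for i in range(1, 10)], dtype=float
        ).T,
    }


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic expression matrix.

    ``planted_pairs`` holds ``(regulator_index, target_index, effect,
    noise_sd)`` tuples: the target tracks the regulator's centred profile
    scaled by ``effect`` plus Gaussian noise, on top of its own baseline.
    Baseline intensities are Gaussian on the log scale (default mean 7,
    SD 1.2, echoing typical log2 microarray magnitudes).
    """

    n_genes: int = 10
    n_samples: int = 20
    planted_pairs: tuple[tuple[int, int, float, float], ...] = ()
    baseline_mu: float = 7.0
    baseline_sd: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 2:
            raise ValueError("need n_genes >= 1 and n_samples >= 2")
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")
        used: set[int] = set()
        for reg, tgt, effect, noise_sd in self.planted_pairs:
            for idx in (reg, tgt):
                if not 0 <= idx < self.n_genes:
                    raise ValueError(f"planted index {idx} out of range")
            if reg == tgt:
                raise ValueError("regulator and target indices must differ")
            if idx_clash := used & {reg, tgt}:
                raise ValueError(f"planted indices reused: {sorted(idx_clash)}")
            used |= {reg, tgt}
            if not np.isfinite(effect):
                raise ValueError("effect must be finite")
            if noise_sd <= 0:
                raise ValueError("noise_sd must be positive")


def generate(spec: SyntheticSpec) -> ExpressionMatrix:
    """Draw one synthetic matrix according to ``spec`` (reproducible by seed).

    Every gene gets its own baseline offset; unplanted genes are i.i.d.
    Gaussian across samples; each planted target is rebuilt as
    ``effect * (regulator - mean(regulator)) + baseline + noise``.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"G{i + 1:03d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{j + 1:03d}" for j in range(spec.n_samples)]
    offsets = rng.normal(0.0, spec.baseline_sd / 2.0, size=spec.n_genes)
    values = (
        spec.baseline_mu
        + offsets[:, None]
        + rng.normal(0.0, spec.baseline_sd, size=(spec.n_genes, spec.n_samples))
    )
    for reg, tgt, effect, noise_sd in spec.planted_pairs:
        regulator = values[reg]
        values[tgt] = (
            spec.baseline_mu
            + offsets[tgt]
            + effect * (regulator - regulator.mean())
            + rng.normal(0.0, noise_sd, size=spec.n_samples)
        )
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(df)


def generate_condition_pair(
    spec_a: SyntheticSpec, spec_b: SyntheticSpec
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Two matrices over the same gene ids with independent planted structure.

    Emulates paired condition inputs (normal vs diseased, adenoma vs
    carcinoma) for network-difference analyses.
    """
    if spec_a.n_genes != spec_b.n_genes:
        raise ValueError(
            f"gene counts differ: {spec_a.n_genes} vs {spec_b.n_genes}"
        )
    return generate(spec_a), generate(spec_b)
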