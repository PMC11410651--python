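"""Mitotic scoring statistics: mis-segregation, FISH attribution, cohesion.

Exact small-sample methods throughout (the assays score 50-100 cells):
Clopper-Pearson intervals for mis-segregation proportions and Fisher's
exact test for between-genotype comparisons.  Cohesion is scored as FISH
focus counts per nucleus: two foci mean cohesed sister chromatids, three
or four mean cohesion loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

CELL_COLUMNS = ["cell", "mis_segregation", "attributed_chromosome"]


def simulate_anaphase(n_cells: int, per_chromosome_probs: Mapping[str, float],
                      seed: int) -> pd.DataFrame:
    """Simulate anaphase scoring with independent per-chromosome failures.

    A cell is abnormal when at least one chromosome mis-segregates; one
    mis-segregating chromosome is attributed uniformly among those that
    failed (FISH attributes a single lagging chromosome per cell).
    """
    chroms = list(per_chromosome_probs)
    probs = np.array([per_chromosome_probs[c] for c in chroms], dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise InputError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fails = rng.random((n_cells, len(chroms))) < probs
    abnormal = fails.any(axis=1)
    # uniform choice among failed chromosomes: argmax of masked random keys
    keys = np.where(fails, rng.random((n_cells, len(chroms))), -1.0)
    choice = np.argmax(keys, axis=1)
    attributed = np.where(abnormal, np.array(chroms, dtype=object)[choice], None)
    return pd.DataFrame(
        {
            "cell": [f"cell{i:05d}" for i in range(n_cells)],
            "mis_segregation": abnormal,
            "attributed_chromosome": attributed,
        }
    )


@dataclass(frozen=True)
class ProportionEstimate:
    successes: int
    n: int
    estimate: float
    ci_low: float
    ci_high: float


def clopper_pearson(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval via beta quantiles."""
    if n <= 0:
        raise InputError("n must be positive")
    if not 0 <= k <= n:
        raise InputError("successes outside [0, n]")
    alpha = 1.0 - confidence
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def missegregation_rate(cells, confidence: float = 0.95) -> ProportionEstimate:
    """Observed mis-segregation proportion with its exact 95% CI.

    ``cells`` is a cell table from :func:`simulate_anaphase`, a boolean
    sequence, or a ``(k, n)`` pair.
    """
    if isinstance(cells, pd.DataFrame):
        flags = cells["mis_segregation"].to_numpy(dtype=bool)
        k, n = int(flags.sum()), flags.size
    elif isinstance(cells, tuple) and len(cells) == 2:
        k, n = int(cells[0]), int(cells[1])
    else:
        flags = np.asarray(list(cells), dtype=bool)
        k, n = int(flags.sum()), flags.size
    if n == 0:
        raise InputError("no cells scored")
    low, high = clopper_pearson(k, n, confidence)
    return ProportionEstimate(k, n, k / n, low, high)


def attribution_distribution(cells: pd.DataFrame) -> dict[str, float]:
    """Fraction of abnormal cells attributed to each chromosome (sums to 1)."""
    abnormal = cells[cells["mis_segregation"]]
    if abnormal.empty:
        raise InputError("no abnormal cells to attribute")
    counts = abnormal["attributed_chromosome"].value_counts()
    total = int(counts.sum())
    return {str(c): counts[c] / total for c in counts.index}


@dataclass(frozen=True)
class FociSummary:
    n: int
    distribution: dict[int, float]   # focus count -> fraction of nuclei
    loss_fraction: float             # P(foci in {3, 4})
    ci_low: float
    ci_high: float


def foci_summary(foci_counts: Sequence[int],
                 confidence: float = 0.95) -> FociSummary:
    """Distribution of FISH focus counts and the cohesion-loss fraction.

    Cohesion loss is defined as more than two foci (two = cohesed sisters);
    one-focus nuclei are reported but excluded from the loss definition.
    """
    counts = np.asarray(list(foci_counts), dtype=int)
    if counts.size == 0:
        raise InputError("no nuclei scored")
    if ((counts < 1) | (counts > 4)).any():
        raise InputError("focus counts must be in {1, 2, 3, 4}")
    n = counts.size
    distribution = {k: float((counts == k).sum()) / n for k in (1, 2, 3, 4)}
    k_loss = int(((counts == 3) | (counts == 4)).sum())
    low, high = clopper_pearson(k_loss, n, confidence)
    return FociSummary(n, distribution, k_loss / n, low, high)


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher's exact p for k1/n1 vs k2/n2."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise InputError("counts must satisfy 0 <= k <= n, n > 0")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
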