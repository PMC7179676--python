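"""Average evolutionary divergence (AED) with Poisson correction.

The conservation statistic is the mean Poisson-corrected distance
d = -ln(1 - p) over all unordered sequence pairs of an alignment, where p is
the per-pair proportion of differing sites after pairwise deletion of
ambiguous positions ('-', 'X', '?').  Standard errors come from bootstrap
resampling of alignment columns (sites) with replacement.

AED is the mean of per-pair Poisson distances, not the Poisson correction of
the mean p.  Pairs with no comparable sites or with p = 1 (the correction's
singularity) are excluded from the mean and counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .alignment_io import MSA

logger = logging.getLogger(__name__)

_AMBIGUOUS = b"-X?"


class UndefinedDistanceError(ValueError):
    """p >= 1 (saturated pair) or no comparable sites."""


class AllPairsUndefinedError(ValueError):
    """Every sequence pair of the alignment was undefined."""


@dataclass(frozen=True)
class PairwiseDistance:
    """Proportion of differing valid sites and its Poisson correction."""

    p: float | None
    n_valid: int
    d: float | None = None

    @property
    def defined(self) -> bool:
        return self.p is not None


@dataclass(frozen=True)
class AEDResult:
    aed: float
    se: float
    n_pairs: int
    n_boot: int
    seed: int | None
    n_excluded: int = 0


@dataclass
class AEDSummary:
    """Per-group AEDs plus the median/overall summaries for one family."""

    per_group: dict[str, AEDResult | None]
    median_aed: float
    overall_aed: AEDResult | None = None
    peptide_overall_aed: AEDResult | None = None
    errors: dict[str, str] = field(default_factory=dict)


def _is_ambiguous(arr: np.ndarray) -> np.ndarray:
    out = np.zeros(arr.shape, dtype=bool)
    for ch in _AMBIGUOUS:
        out |= arr == ch
    return out


def pairwise_p_distance(row_a: str, row_b: str) -> PairwiseDistance:
    """p-distance of two aligned rows under pairwise deletion.

    Sites where either row holds '-', 'X' or '?' are deleted; p is the
    fraction of remaining sites that differ.  With no comparable sites the
    pair is flagged undefined (``p is None``).
    """
    if len(row_a) != len(row_b):
        raise ValueError(f"row lengths differ: {len(row_a)} vs {len(row_b)}")
    a = np.frombuffer(row_a.encode(), dtype=np.uint8)
    b = np.frombuffer(row_b.encode(), dtype=np.uint8)
    valid = ~(_is_ambiguous(a) | _is_ambiguous(b))
    n_valid = int(valid.sum())
    if n_valid == 0:
        logger.warning("pair with no comparable sites excluded from AED")
        return PairwiseDistance(None, 0)
    p = float(((a != b) & valid).sum() / n_valid)
    return PairwiseDistance(p, n_valid)


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance d = -ln(1 - p) for 0 <= p < 1."""
    if not (0.0 <= p < 1.0):
        raise UndefinedDistanceError(
            f"Poisson correction undefined for p = {p} (requires 0 <= p < 1)"
        )
    return -math.log1p(-p)


def _pair_tables(msa: MSA) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-pair boolean difference/validity tables over columns."""
    arr = np.array(
        [np.frombuffer(r.encode(), dtype=np.uint8) for r in msa.rows]
    )
    amb = _is_ambiguous(arr)
    pairs = list(combinations(range(msa.n_rows), 2))
    i = np.array([p[0] for p in pairs])
    j = np.array([p[1] for p in pairs])
    valid = ~(amb[i] | amb[j])
    diff = (arr[i] != arr[j]) & valid
    return diff, valid, len(pairs)


def _mean_poisson(diff: np.ndarray, valid: np.ndarray) -> tuple[float, int]:
    """Mean per-pair Poisson distance; excluded (undefined) pair count."""
    nv = valid.sum(axis=1)
    nd = diff.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(nv > 0, nd / np.maximum(nv, 1), np.nan)
    defined = (nv > 0) & (p < 1.0)
    if not defined.any():
        return math.nan, int(len(p))
    d = -np.log1p(-p[defined])
    return float(d.mean()), int((~defined).sum())


def average_evolutionary_divergence(
    msa: MSA, n_boot: int = 500, seed: int | None = None
) -> AEDResult:
    """AED over all sequence pairs with a column-bootstrap standard error.

    Each of the ``n_boot`` replicates resamples alignment columns with
    replacement (seeded RNG); the SE is the sample standard deviation of the
    replicate AEDs.  Undefined pairs are excluded from the mean with a logged
    count rather than aborting.
    """
    if msa.n_rows < 2:
        raise ValueError("AED requires at least 2 sequences")
    if msa.n_cols == 0:
        raise ValueError("AED requires at least 1 column")
    diff, valid, n_pairs = _pair_tables(msa)
    aed, n_excluded = _mean_poisson(diff, valid)
    if math.isnan(aed):
        raise AllPairsUndefinedError("all sequence pairs undefined (no comparable sites or p = 1)")
    if n_excluded:
        logger.warning("%d undefined pair(s) excluded from AED", n_excluded)
    rng = np.random.default_rng(seed)
    m = msa.n_cols
    reps = np.empty(max(n_boot, 0))
    for b in range(n_boot):
        idx = rng.integers(0, m, size=m)
        reps[b] = _mean_poisson(diff[:, idx], valid[:, idx])[0]
    finite = reps[np.isfinite(reps)]
    se = float(finite.std(ddof=1)) if finite.size > 1 else 0.0
    return AEDResult(aed, se, n_pairs, n_boot, seed, n_excluded)


def median_of(values: Sequence[float]) -> float:
    """Median; an even count yields the mean of the two central values."""
    if not values:
        raise ValueError("median of empty sequence")
    return float(np.median(np.asarray(values, dtype=float)))


def summarize_family(
    per_group_msas: Mapping[str, MSA],
    merged: MSA | None = None,
    peptide_columns: MSA | None = None,
    n_boot: int = 500,
    seed: int | None = None,
) -> AEDSummary:
    """Per-group AED, the median across groups, and the overall statistics.

    Group-level failures (e.g. a group with a single sequence) are recorded
    under ``errors`` without aborting the remaining groups.  Group bootstraps
    use independent streams spawned from ``seed``.
    """
    if not per_group_msas:
        raise ValueError("summarize_family requires at least one group")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(per_group_msas) + 2)
    per_group: dict[str, AEDResult | None] = {}
    errors: dict[str, str] = {}
    for (group, msa), child in zip(per_group_msas.items(), children):
        try:
            child_seed = int(child.generate_state(1)[0] % (2**31))
            per_group[group] = average_evolutionary_divergence(
                msa, n_boot=n_boot, seed=child_seed
            )
        except (ValueError, AllPairsUndefinedError) as exc:
            logger.warning("group %s skipped: %s", group, exc)
            per_group[group] = None
            errors[group] = str(exc)
    aeds = [r.aed for r in per_group.values() if r is not None]
    if not aeds:
        raise AllPairsUndefinedError("no group yielded a defined AED")
    overall = None
    if merged is not None:
        seed_o = int(children[-2].generate_state(1)[0] % (2**31))
        overall = average_evolutionary_divergence(merged, n_boot=n_boot, seed=seed_o)
    peptide_overall = None
    if peptide_columns is not None:
        seed_p = int(children[-1].generate_state(1)[0] % (2**31))
        peptide_overall = average_evolutionary_divergence(
            peptide_columns, n_boot=n_boot, seed=seed_p
        )
    return AEDSummary(
        per_group=per_group,
        median_aed=median_of(aeds),
        overall_aed=overall,
        peptide_overall_aed=peptide_overall,
        errors=errors,
    )
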