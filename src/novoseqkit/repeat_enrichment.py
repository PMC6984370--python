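"""Nonparametric permutation test for repeat-class composition.

Two sequence sets A and B (A at least twice the size of B) are compared
per repeat class by the statistic Diff_rep = |A_rep% - B_rep%|, where the
percentages are base-weighted (pooled masked bases over pooled sequence
length).  The null distribution comes from random subsets R of A with
|R| = |B|, drawn without replacement, scored as Diff_Rrep = |A_rep% -
R_rep%| against the FULL set A exactly as the observed statistic is; the
p-value is the fraction of subsets with Diff_Rrep > Diff_rep (strict, so
ties do not count; an optional add-one correction is available).

A background sampler represents a reference genome as n random intervals
whose sizes follow a supplied empirical size distribution, with repeat
content looked up from the reference's repeat track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import REPEAT_CLASSES, GenomicInterval, RepeatAnnotation

__all__ = [
    "RepeatProfile",
    "PermutationResult",
    "BackgroundSample",
    "annotations_to_matrix",
    "composition_of_set",
    "diff_rep",
    "permutation_test",
    "sample_background",
]


@dataclass
class RepeatProfile:
    """Base-weighted percentage of each repeat class in a sequence set."""

    percentages: dict[str, float]
    total_bases: int

    def __post_init__(self) -> None:
        total = sum(self.percentages.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"percentages sum to {total}, not 100")
        if any(v < 0 for v in self.percentages.values()):
            raise ValueError("negative percentage")


@dataclass
class PermutationResult:
    observed_diff: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    seed: int | None

    @property
    def resolution(self) -> float:
        return 1.0 / self.n_permutations


def annotations_to_matrix(annotations: list[RepeatAnnotation]) -> np.ndarray:
    """(n_sequences, n_classes) base-count matrix in REPEAT_CLASSES order."""
    mat = np.zeros((len(annotations), len(REPEAT_CLASSES)), dtype=np.float64)
    idx = {c: i for i, c in enumerate(REPEAT_CLASSES)}
    for row, ann in enumerate(annotations):
        for cls, n in ann.class_base_counts().items():
            mat[row, idx[cls]] = n
    return mat


def _as_matrix(seq_set) -> np.ndarray:
    if isinstance(seq_set, np.ndarray):
        return seq_set
    return annotations_to_matrix(list(seq_set))


def _pct(mat: np.ndarray) -> np.ndarray:
    totals = mat.sum()
    if totals <= 0:
        raise ValueError("sequence set has no bases")
    return 100.0 * mat.sum(axis=0) / totals


def composition_of_set(annotations) -> RepeatProfile:
    """Pooled (base-weighted, not contig-averaged) repeat composition."""
    mat = _as_matrix(annotations)
    if mat.shape[0] == 0:
        raise ValueError("empty sequence set")
    pct = _pct(mat)
    return RepeatProfile(
        percentages=dict(zip(REPEAT_CLASSES, pct.tolist())),
        total_bases=int(mat.sum()),
    )


def diff_rep(profile_a: RepeatProfile, profile_b: RepeatProfile) -> dict[str, float]:
    """Per-class |A_rep% - B_rep%| (symmetric, nonnegative)."""
    return {
        c: abs(profile_a.percentages[c] - profile_b.percentages[c])
        for c in REPEAT_CLASSES
    }


def _sample_without_replacement(
    rng: np.random.Generator, n_total: int, size: int
) -> np.ndarray:
    """Uniform subset of ``size`` indices; rejection sampling when the
    subset is small relative to the population."""
    if size > n_total:
        raise ValueError("subset larger than population")
    if size * 8 >= n_total:
        return rng.choice(n_total, size=size, replace=False)
    picked = np.unique(rng.integers(0, n_total, size=int(size * 1.3) + 16))
    while len(picked) < size:
        more = rng.integers(0, n_total, size=size)
        picked = np.unique(np.concatenate([picked, more]))
    return rng.permutation(picked)[:size]


def permutation_test(
    set_a,
    set_b,
    n_permutations: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    add_one_correction: bool = False,
) -> PermutationResult:
    """Permutation test of per-class composition differences.

    Set A must contain at least twice as many sequences as set B; if not,
    the sets are swapped, and an error is raised if neither ordering
    qualifies.  With ``add_one_correction`` the p-value is (k+1)/(n+1)
    instead of k/n.
    """
    mat_a, mat_b = _as_matrix(set_a), _as_matrix(set_b)
    if mat_b.shape[0] == 0 or mat_a.shape[0] == 0:
        raise ValueError("empty sequence set")
    if mat_a.shape[0] < 2 * mat_b.shape[0]:
        mat_a, mat_b = mat_b, mat_a
        if mat_a.shape[0] < 2 * mat_b.shape[0]:
            raise ValueError(
                "neither set is at least twice the size of the other "
                f"({mat_a.shape[0]} vs {mat_b.shape[0]})"
            )
    if rng is None:
        rng = np.random.default_rng(seed)
    pct_a = _pct(mat_a)
    observed = np.abs(pct_a - _pct(mat_b))

    n_a, n_b = mat_a.shape[0], mat_b.shape[0]
    exceed = np.zeros(len(REPEAT_CLASSES), dtype=np.int64)
    for _ in range(n_permutations):
        idx = _sample_without_replacement(rng, n_a, n_b)
        sub = mat_a[idx]
        diff_r = np.abs(pct_a - _pct(sub))
        exceed += diff_r > observed
    if add_one_correction:
        p = (exceed + 1) / (n_permutations + 1)
    else:
        p = exceed / n_permutations
    return PermutationResult(
        observed_diff=dict(zip(REPEAT_CLASSES, observed.tolist())),
        p_values=dict(zip(REPEAT_CLASSES, p.tolist())),
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# background sampler
# ---------------------------------------------------------------------------


@dataclass
class BackgroundSample:
    """n random reference intervals with per-interval repeat base counts
    (columns in REPEAT_CLASSES order)."""

    chrom_names: list[str]
    chrom_idx: np.ndarray
    starts: np.ndarray
    lengths: np.ndarray
    counts: np.ndarray  # (n, n_classes)

    def intervals(self):
        for ci, s, ln in zip(self.chrom_idx, self.starts, self.lengths):
            yield GenomicInterval(self.chrom_names[ci], int(s), int(s + ln))


def sample_background(
    chrom_lengths: dict[str, int],
    repeat_track: list[GenomicInterval],
    size_distribution,
    n: int = 500_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BackgroundSample:
    """Represent a reference as n random intervals.

    Chromosomes are drawn proportionally to length, starts uniformly over
    the valid range, and interval sizes with replacement from the
    empirical ``size_distribution``.  Repeat content is looked up from
    the reference's repeat track via per-class prefix sums.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    sizes = np.asarray(list(size_distribution), dtype=np.int64)
    if sizes.size == 0 or sizes.min() <= 0:
        raise ValueError("size distribution must be non-empty and positive")
    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64)
    if sizes.max() > lens.max():
        raise ValueError("reference shorter than the largest sampled size")
    if rng is None:
        rng = np.random.default_rng(seed)

    class_idx = {c: i for i, c in enumerate(REPEAT_CLASSES)}
    # per-chrom per-class prefix sums of masked bases
    prefix: dict[str, np.ndarray] = {}
    for ci, chrom in enumerate(chroms):
        cover = np.zeros((len(REPEAT_CLASSES), lens[ci] + 1), dtype=np.int32)
        for iv in repeat_track:
            if iv.chrom == chrom and iv.label in class_idx:
                cover[class_idx[iv.label], iv.start + 1 : iv.end + 1] = 1
        prefix[chrom] = np.cumsum(cover, axis=1)

    length_draw = sizes[rng.integers(0, len(sizes), size=n)]
    chrom_draw = rng.choice(len(chroms), size=n, p=lens / lens.sum())
    # redraw chromosomes too short for the drawn length
    bad = length_draw > lens[chrom_draw]
    while bad.any():
        chrom_draw[bad] = rng.choice(len(chroms), size=int(bad.sum()), p=lens / lens.sum())
        bad = length_draw > lens[chrom_draw]
    starts = (rng.random(n) * (lens[chrom_draw] - length_draw + 1)).astype(np.int64)

    counts = np.zeros((n, len(REPEAT_CLASSES)), dtype=np.float64)
    for ci, chrom in enumerate(chroms):
        mask = chrom_draw == ci
        if not mask.any():
            continue
        s, e = starts[mask], starts[mask] + length_draw[mask]
        pre = prefix[chrom]
        masked = (pre[:, e] - pre[:, s]).T  # (n_mask, n_classes)
        counts[mask, :] = masked
    counts[:, class_idx["Unmasked"]] = length_draw - counts.sum(axis=1)
    return BackgroundSample(
        chrom_names=chroms,
        chrom_idx=chrom_draw,
        starts=starts,
        lengths=length_draw,
        counts=counts,
    )
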