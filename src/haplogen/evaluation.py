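"""Realism, novelty, and coherence measures for synthetic haplotype populations.

Covers: per-variant frequency drift and disappearing mutations, signed pairwise
linkage disequilibrium (Pearson r over haplotype indicator columns), the edit
score (normalized Hamming distance to nearest reference neighbours) used as a
privacy audit, a section-shuffle control for cross-section coherence, and
ancestry-switch metaprofiles summarising chromosome-painting output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA

from .compression import binarize, decode_sections
from .generation import Checkpoint, generate
from .io_formats import HaplotypeMatrix
from .segmentation import SegmentationPlan

__all__ = [
    "allele_frequencies",
    "FreqDriftReport",
    "freq_drift",
    "ld_matrix",
    "edit_score",
    "NoveltyReport",
    "novelty_trend",
    "shuffle_sections",
    "CoherenceReport",
    "coherence_test",
    "ancestry_switch_metaprofile",
    "read_paintings",
    "metaprofile_correlation",
    "split_bin_accuracy_test",
    "score_checkpoint",
    "select_checkpoint",
]


def allele_frequencies(hm: HaplotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-variant allele frequency: column mean over haplotypes."""
    data = hm.data if isinstance(hm, HaplotypeMatrix) else np.asarray(hm)
    return data.mean(axis=0)


@dataclass
class FreqDriftReport:
    drift: np.ndarray  # per-variant |f_ref - f_syn|
    mean_drift: float
    max_drift: float
    n_disappeared: int  # variants present in the reference but absent synthetic


def _as_data(x) -> np.ndarray:
    return x.data if isinstance(x, HaplotypeMatrix) else np.asarray(x)


def freq_drift(ref: HaplotypeMatrix | np.ndarray, syn: HaplotypeMatrix | np.ndarray) -> FreqDriftReport:
    """Absolute per-variant frequency difference plus the disappearing-variant count."""
    if isinstance(ref, HaplotypeMatrix) and isinstance(syn, HaplotypeMatrix):
        if list(ref.variant_ids) != list(syn.variant_ids):
            raise ValueError("reference and synthetic variant sets differ")
    r, s = _as_data(ref), _as_data(syn)
    if r.shape[1] != s.shape[1]:
        raise ValueError("variant count mismatch")
    f_ref = r.mean(axis=0)
    f_syn = s.mean(axis=0)
    drift = np.abs(f_ref - f_syn)
    n_disappeared = int(np.sum((f_ref > 0) & (f_syn == 0)))
    return FreqDriftReport(drift=drift, mean_drift=float(drift.mean()),
                           max_drift=float(drift.max()), n_disappeared=n_disappeared)


def ld_matrix(hm: HaplotypeMatrix | np.ndarray,
              range_a: tuple[int, int] | None = None,
              range_b: tuple[int, int] | None = None,
              statistic: str = "r") -> np.ndarray:
    """Signed pairwise LD block between allele columns.

    ``statistic="r"`` (default) is the Pearson correlation of allele
    indicators; ``statistic="dprime"`` is the signed D' (D normalised by its
    attainable extreme given the allele frequencies).  Monomorphic columns
    yield 0 by convention.  With both ranges given, returns the (a x b) cross
    block; with none, the full M x M matrix.
    """
    if statistic not in ("r", "dprime"):
        raise ValueError("statistic must be 'r' or 'dprime'")
    data = _as_data(hm).astype(float)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 haplotypes")
    m = data.shape[1]
    range_a = range_a or (0, m)
    range_b = range_b or range_a
    a = data[:, range_a[0]:range_a[1]]
    b = data[:, range_b[0]:range_b[1]]
    pa = a.mean(axis=0)
    pb = b.mean(axis=0)
    d = a.T @ b / data.shape[0] - np.outer(pa, pb)  # covariance of indicators
    if statistic == "r":
        denom = np.outer(a.std(axis=0), b.std(axis=0))
    else:
        # D' denominator: min(pa*pb, qa*qb) for D<0, min(pa*qb, qa*pb) for D>0
        qa, qb = 1.0 - pa, 1.0 - pb
        neg = np.minimum(np.outer(pa, pb), np.outer(qa, qb))
        pos = np.minimum(np.outer(pa, qb), np.outer(qa, pb))
        denom = np.where(d >= 0, pos, neg)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, d / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(out, -1.0, 1.0)


def edit_score(syn_sample: np.ndarray, reference: HaplotypeMatrix | np.ndarray, k: int = 3) -> np.ndarray:
    """The k smallest normalized Hamming distances from a sample to reference rows."""
    ref = _as_data(reference)
    sample = np.asarray(syn_sample).ravel()
    if sample.shape[0] != ref.shape[1]:
        raise ValueError("sample length does not match reference variant count")
    if k > ref.shape[0]:
        raise ValueError("k exceeds the number of reference haplotypes")
    d = (sample[None, :] != ref).mean(axis=1)
    return np.sort(np.partition(d, k - 1)[:k])


@dataclass
class NoveltyReport:
    """Nearest-neighbour edit-score distributions for reference and synthetic rows.

    ``*_scores`` are (n, k) arrays of ascending neighbour distances;
    ``jump_ratio`` = (2nd-NN mean - 1st-NN mean) / (3rd-NN mean - 2nd-NN mean)
    for the synthetic rows — a large value with near-zero 1st-NN scores flags
    the copy-with-minor-edits scenario.
    """

    ref_scores: np.ndarray
    syn_scores: np.ndarray
    ref_means: np.ndarray
    syn_means: np.ndarray
    jump_ratio: float
    min_first_nn: float


def _nearest_k(dist: np.ndarray, k: int) -> np.ndarray:
    return np.sort(np.partition(dist, k - 1, axis=1)[:, :k], axis=1)


def novelty_trend(ref: HaplotypeMatrix | np.ndarray, syn: HaplotypeMatrix | np.ndarray,
                  k: int = 3) -> NoveltyReport:
    """Edit scores to 1st..kth nearest reference neighbours for both populations.

    Reference rows are compared to the other reference rows (self excluded);
    synthetic rows to all reference rows.
    """
    r = _as_data(ref).astype(np.uint8)
    s = _as_data(syn).astype(np.uint8)
    if r.shape[1] != s.shape[1]:
        raise ValueError("variant count mismatch")
    d_rr = cdist(r, r, metric="hamming")
    np.fill_diagonal(d_rr, np.inf)
    d_sr = cdist(s, r, metric="hamming")
    ref_scores = _nearest_k(d_rr, k)
    syn_scores = _nearest_k(d_sr, k)
    ref_means = ref_scores.mean(axis=0)
    syn_means = syn_scores.mean(axis=0)
    num = syn_means[1] - syn_means[0]
    den = syn_means[2] - syn_means[1]
    jump = float(num / den) if den > 0 else float("inf")
    return NoveltyReport(ref_scores=ref_scores, syn_scores=syn_scores,
                         ref_means=ref_means, syn_means=syn_means,
                         jump_ratio=jump, min_first_nn=float(syn_scores[:, 0].min()))


def shuffle_sections(syn: HaplotypeMatrix, plan: SegmentationPlan, seed: int = 0) -> HaplotypeMatrix:
    """Independently permute row order within each section's column block.

    Destroys cross-section associations while leaving every per-variant
    frequency (and every within-section LD pattern) unchanged.
    """
    plan.validate(syn.n_variants)
    rng = np.random.default_rng(seed)
    data = syn.data.copy()
    for sec in plan.sections:
        perm = rng.permutation(syn.n_haplotypes)
        data[:, sec.start:sec.end] = syn.data[perm, sec.start:sec.end]
    return HaplotypeMatrix(chrom=syn.chrom, positions=syn.positions.copy(),
                           variant_ids=list(syn.variant_ids),
                           sample_ids=list(syn.sample_ids), data=data)


def _flat_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    if a.std() == 0 or b.std() == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class CoherenceReport:
    """Cross-section LD-pattern agreement of synthetic vs shuffled-synthetic data.

    For every adjacent section pair the reference cross-block LD matrix is
    correlated with the synthetic (resp. shuffled-synthetic) cross-block; a
    coherent generator scores strictly higher than its shuffled control.
    """

    corr_synthetic: float
    corr_shuffled: float
    per_pair_synthetic: list[float] = field(default_factory=list)
    per_pair_shuffled: list[float] = field(default_factory=list)
    pca_reference: np.ndarray | None = None
    pca_synthetic: np.ndarray | None = None
    pca_shuffled: np.ndarray | None = None


def coherence_test(ref: HaplotypeMatrix, syn: HaplotypeMatrix, plan: SegmentationPlan,
                   seed: int = 0, n_components: int = 2) -> CoherenceReport:
    """Compare cross-section LD conservation of synthetic data against a shuffle control.

    Also fits a PCA on the reference population only and projects the
    reference, synthetic, and shuffled datasets into that space for plotting.
    """
    shuffled = shuffle_sections(syn, plan, seed=seed)
    per_syn: list[float] = []
    per_shuf: list[float] = []
    for left, right in zip(plan.sections, plan.sections[1:]):
        ra = (left.start, left.end)
        rb = (right.start, right.end)
        block_ref = ld_matrix(ref, ra, rb)
        per_syn.append(_flat_corr(block_ref, ld_matrix(syn, ra, rb)))
        per_shuf.append(_flat_corr(block_ref, ld_matrix(shuffled, ra, rb)))
    corr_syn = float(np.mean(per_syn)) if per_syn else float("nan")
    corr_shuf = float(np.mean(per_shuf)) if per_shuf else float("nan")
    n_comp = min(n_components, ref.n_haplotypes, ref.n_variants)
    pca = PCA(n_components=n_comp, random_state=0).fit(ref.data.astype(float))
    return CoherenceReport(
        corr_synthetic=corr_syn, corr_shuffled=corr_shuf,
        per_pair_synthetic=per_syn, per_pair_shuffled=per_shuf,
        pca_reference=pca.transform(ref.data.astype(float)),
        pca_synthetic=pca.transform(syn.data.astype(float)),
        pca_shuffled=pca.transform(shuffled.data.astype(float)),
    )


def ancestry_switch_metaprofile(paintings: Sequence[Sequence] | np.ndarray) -> np.ndarray:
    """Per-position ancestry switch frequency over a set of painted samples.

    Input: one label sequence per sample (all the same length).  Output length
    equals the sequence length; position 0 is always 0 and position i holds the
    fraction of samples whose label at i differs from their label at i-1.
    """
    seqs = list(paintings)
    if not seqs:
        raise ValueError("no painting sequences given")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("ragged painting sequences: all must have the same length")
    arr = np.asarray([list(s) for s in seqs])
    profile = np.zeros(arr.shape[1])
    if arr.shape[1] > 1:
        profile[1:] = (arr[:, 1:] != arr[:, :-1]).mean(axis=0)
    return profile


def read_paintings(path) -> tuple[list[str], np.ndarray]:
    """Read per-sample ancestry label sequences from a TSV.

    Each row: sample identifier, then one ancestry label per variant.
    Returns (sample ids, labels array) ready for
    :func:`ancestry_switch_metaprofile`.
    """
    samples: list[str] = []
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            samples.append(cols[0])
            rows.append(cols[1:])
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError("ragged painting rows: all samples need one label per variant")
    return samples, np.asarray(rows)


def metaprofile_correlation(ref_profile: np.ndarray, syn_profile: np.ndarray) -> float:
    """Pearson correlation between two switch-frequency profiles."""
    ref_profile = np.asarray(ref_profile, dtype=float)
    syn_profile = np.asarray(syn_profile, dtype=float)
    if ref_profile.shape != syn_profile.shape:
        raise ValueError("profiles must have the same length")
    return _flat_corr(ref_profile, syn_profile)


def split_bin_accuracy_test(accuracies: Sequence[float], split_flags: Sequence[bool]):
    """Mann-Whitney U test: are hotspot-split bins reconstructed less accurately?

    One-sided (split < intact); returns the scipy result object.
    """
    acc = np.asarray(accuracies, dtype=float)
    flags = np.asarray(split_flags, dtype=bool)
    if len(acc) != len(flags):
        raise ValueError("accuracies and split_flags must align")
    split, intact = acc[flags], acc[~flags]
    if split.size == 0 or intact.size == 0:
        raise ValueError("need both split and intact bins")
    return mannwhitneyu(split, intact, alternative="less")


def score_checkpoint(checkpoint: Checkpoint, models: Sequence, ref: HaplotypeMatrix,
                     plan: SegmentationPlan, n: int = 100, seed: int = 0) -> float:
    """Realism score of a checkpoint: within-section LD correlation minus mean drift.

    Generates ``n`` samples, decodes and binarizes them, then combines the mean
    per-section LD-pattern correlation with the reference and the mean
    per-variant frequency drift (higher is better).
    """
    latent = generate(checkpoint, n, seed=seed)
    decoded = binarize(decode_sections(models, latent, checkpoint.section_offsets))
    drift = freq_drift(ref.data, decoded).mean_drift
    corrs = []
    for sec in plan.sections:
        rng_sec = (sec.start, sec.end)
        corrs.append(_flat_corr(ld_matrix(ref, rng_sec, rng_sec),
                                ld_matrix(decoded, rng_sec, rng_sec)))
    return float(np.mean(corrs) - drift)


def select_checkpoint(checkpoints: Sequence[Checkpoint], models: Sequence,
                      ref: HaplotypeMatrix, plan: SegmentationPlan,
                      n: int = 100, seed: int = 0) -> Checkpoint:
    """Pick the checkpoint with the best realism score."""
    scores = [score_checkpoint(c, models, ref, plan, n=n, seed=seed) for c in checkpoints]
    return checkpoints[int(np.argmax(scores))]
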