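"""Trinucleotide mutation profiles and signature refitting.

A profile is the count vector of single-base substitutions over the 96
pyrimidine-centred trinucleotide classes (optionally with a descriptive
+/-2 bp extended context tally). Catalog signatures are ranked against the
profile by cosine similarity, and contributions are fit by non-negative
least squares (NNLS) on raw counts, so contributions are absolute mutation
counts. Backwards elimination repeatedly drops the lowest-contribution
signature and refits, stopping before a removal would drop the
reconstruction cosine more than ``max_delta`` below the full-catalog fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .contexts import CONTEXT_INDEX, CONTEXTS_96, collapse_substitution
from .io import SignatureSet


class ReferenceMismatchError(ValueError):
    """The variant's stated reference base disagrees with the FASTA."""


@dataclass
class MutationProfile:
    counts: np.ndarray  # length 96, canonical order
    n: int
    extended_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("profile must have 96 entries")
        if (self.counts < 0).any():
            raise ValueError("negative profile count")


@dataclass
class RefitResult:
    selected: list[str]
    contributions: np.ndarray  # per selected signature, mutation counts
    similarity_trajectory: list[tuple[int, float]]  # (k remaining, cosine)
    final_cosine: float


def _fetch(reference, chrom: str, start0: int, end0: int) -> str:
    """Uppercase reference slice [start0, end0); works for a pyfaidx Fasta
    or a plain dict of sequence strings."""
    return str(reference[chrom][max(start0, 0):end0]).upper()


def trinucleotide_context(chrom: str, pos: int, ref: str, alt: str,
                          reference) -> str | None:
    """Pyrimidine-centred 96-class label for one SNV, or None when a flank
    contains N (such variants are excluded with a warning)."""
    tri = _fetch(reference, chrom, pos - 2, pos + 1)
    if len(tri) != 3:
        raise ReferenceMismatchError(
            f"reference does not cover {chrom}:{pos}+/-1")
    if tri[1] != ref:
        raise ReferenceMismatchError(
            f"reference base {tri[1]} != variant ref {ref} at {chrom}:{pos}")
    if "N" in tri:
        warnings.warn(f"N in flank at {chrom}:{pos}; variant excluded")
        return None
    return collapse_substitution(tri[0], ref, alt, tri[2])


def extended_context(chrom: str, pos: int, ref: str, alt: str,
                     reference, flank: int = 2) -> str | None:
    """Pyrimidine-collapsed context with ``flank`` bases each side, e.g.
    "AG[C>T]GA" for flank=2."""
    seq = _fetch(reference, chrom, pos - 1 - flank, pos + flank)
    if len(seq) != 2 * flank + 1 or "N" in seq:
        return None
    five, center, three = seq[:flank], seq[flank], seq[flank + 1:]
    if center != ref:
        raise ReferenceMismatchError(
            f"reference base {center} != variant ref {ref} at {chrom}:{pos}")
    if ref in ("A", "G"):
        from .contexts import revcomp
        five, three = revcomp(three), revcomp(five)
        ref, alt = revcomp(ref), revcomp(alt)
    return f"{five}[{ref}>{alt}]{three}"


def build_profile(candidates, reference, extended_flank: int = 0
                  ) -> MutationProfile:
    """Count SNV candidates into a 96-class profile.

    ``candidates`` need ``chrom``/``pos``/``ref``/``alt`` attributes; only
    single-base substitutions contribute. With ``extended_flank=2`` a
    5-base-context tally is filled as well (descriptive only; it plays no
    role in fitting).
    """
    counts = np.zeros(96)
    extended: dict[str, int] = {}
    n = 0
    for cand in candidates:
        if len(cand.ref) != 1 or len(cand.alt) != 1:
            continue
        label = trinucleotide_context(cand.chrom, cand.pos, cand.ref,
                                      cand.alt, reference)
        if label is None:
            continue
        counts[CONTEXT_INDEX[label]] += 1
        n += 1
        if extended_flank:
            ext = extended_context(cand.chrom, cand.pos, cand.ref, cand.alt,
                                   reference, flank=extended_flank)
            if ext is not None:
                extended[ext] = extended.get(ext, 0) + 1
    return MutationProfile(counts=counts, n=n, extended_counts=extended)


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two non-negative profile vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(a @ b / (na * nb))


def nnls_refit(profile: MutationProfile, signatures: SignatureSet,
               names: list[str] | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative least-squares fit of catalog signatures to the profile.

    Returns (contributions, reconstruction); contributions are on the raw
    count scale of the profile.
    """
    names = names if names is not None else signatures.names
    matrix = signatures.matrix[names].to_numpy()
    contributions, _ = optimize.nnls(matrix, profile.counts)
    return contributions, matrix @ contributions


def rank_signatures(profile: MutationProfile, signatures: SignatureSet
                    ) -> list[tuple[str, float]]:
    """Catalog signatures sorted by cosine similarity to the profile,
    descending; ties keep catalog order (stable sort)."""
    sims = [(name, cosine_similarity(profile.counts, signatures.column(name)))
            for name in signatures.names]
    return sorted(sims, key=lambda item: -item[1])


def backwards_selection(profile: MutationProfile, signatures: SignatureSet,
                        max_delta: float = 0.004) -> RefitResult:
    """Iterative NNLS refit with backwards elimination.

    Starting from the full catalog, the lowest-contribution signature is
    removed and the remainder refit; elimination stops before a removal
    that would drop the reconstruction cosine by more than ``max_delta``
    from the initial full-catalog cosine.
    """
    if not signatures.names:
        raise ValueError("empty signature catalog")
    selected = list(signatures.names)
    contributions, reconstruction = nnls_refit(profile, signatures, selected)
    base_cosine = cosine_similarity(profile.counts, reconstruction)
    trajectory = [(len(selected), base_cosine)]
    cosine = base_cosine
    while len(selected) > 1:
        drop = int(np.argmin(contributions))
        trial = selected[:drop] + selected[drop + 1:]
        trial_contrib, trial_recon = nnls_refit(profile, signatures, trial)
        trial_cosine = cosine_similarity(profile.counts, trial_recon)
        if base_cosine - trial_cosine > max_delta:
            break
        selected, contributions, cosine = trial, trial_contrib, trial_cosine
        trajectory.append((len(selected), cosine))
    return RefitResult(selected=selected, contributions=contributions,
                       similarity_trajectory=trajectory, final_cosine=cosine)


def profile_table(profile: MutationProfile):
    """96-row (context, count) table in canonical order."""
    import pandas as pd

    return pd.DataFrame({"context": list(CONTEXTS_96),
                         "count": profile.counts.astype(int)})


def plot_profile(profile: MutationProfile, path: str) -> None:
    """Standard 96-bar profile plot, one color block per substitution type."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .contexts import SUBSTITUTION_TYPES

    colors = ["#03BCEE", "#010101", "#E32926", "#CAC9C9", "#A1CE63",
              "#EBC6C4"]
    fig, ax = plt.subplots(figsize=(10, 2.6))
    for i, sub in enumerate(SUBSTITUTION_TYPES):
        sl = slice(16 * i, 16 * (i + 1))
        ax.bar(range(16 * i, 16 * (i + 1)), profile.counts[sl],
               color=colors[i], width=0.7, label=sub)
    ax.set_xticks([])
    ax.set_ylabel("count")
    ax.legend(ncol=6, fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
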