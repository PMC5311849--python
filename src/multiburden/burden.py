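"""Minor-allele orientation, rare-variant filtering, and regional collapsing.

A region's rare variants are collapsed per individual into the proportion of
minor alleles carried, ``z_i``.  With ``r_i`` the individual's minor-allele
count summed over the region's rare variants and ``n_i`` the number of those
variants successfully genotyped or imputed for the individual, the default
proportion is computed over allele copies, ``z_i = r_i / (2 n_i)``, which
keeps ``z_i`` in [0, 1]; a switch restores the literal per-variant ratio
``r_i / n_i``.  The choice only rescales the regression intercept and slopes
by one half — likelihood-ratio p-values, BIC and model ranking are
unchanged.  The regression weight is ``w_i = n_i``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import RegionSkipped
from .formats import Region, VariantRecord

__all__ = [
    "OrientedVariant",
    "BurdenVector",
    "allele_b_frequency",
    "orient_minor",
    "variant_passes_filters",
    "expected_dosage",
    "threshold_call",
    "build_burden",
]


@dataclass
class OrientedVariant:
    """A variant with its sample minor-allele frequency and orientation."""

    variant: VariantRecord
    maf: float
    minor_is_allele_b: bool


def allele_b_frequency(
    variant: VariantRecord, include_mask: np.ndarray | None = None
) -> float:
    """Sample frequency of allele B from expected dosages.

    The expected allele-B dose of a triplet is ``pAB + 2·pBB``; the
    frequency is its mean over non-missing (included) individuals divided
    by two.  Returns NaN when every included triplet is missing, which
    callers treat as "drop this variant".
    """
    probs = variant.probs
    if include_mask is not None:
        probs = probs[include_mask]
    ok = ~np.isnan(probs[:, 0])
    if not ok.any():
        return float("nan")
    dose_b = probs[ok, 1] + 2.0 * probs[ok, 2]
    return float(dose_b.mean() / 2.0)


def orient_minor(variant: VariantRecord, freq_b: float) -> OrientedVariant:
    """Designate the minor allele; a tie at frequency 0.5 designates B."""
    minor_is_b = freq_b <= 0.5
    maf = min(freq_b, 1.0 - freq_b)
    return OrientedVariant(variant, maf, minor_is_b)


def variant_passes_filters(
    oriented: OrientedVariant,
    region: Region,
    rare_thresh: float,
    extract_set: set[str] | None = None,
    exclude_set: set[str] | None = None,
) -> tuple[bool, str]:
    """Rare-variant inclusion predicate; returns (passes, reason).

    A variant is used when it lies inside the region, is polymorphic with
    MAF strictly below ``rare_thresh`` (the "< 5%" rule is strict), and
    survives the rs-ID extract/exclude lists.
    """
    v = oriented.variant
    if not region.contains(v.position):
        return False, "outside region"
    if exclude_set and v.rs_id in exclude_set:
        return False, "excluded by list"
    if extract_set and v.rs_id not in extract_set:
        return False, "not in extract list"
    if oriented.maf == 0.0:
        return False, "monomorphic"
    if not oriented.maf < rare_thresh:
        return False, f"MAF {oriented.maf:.4g} >= rare_thresh {rare_thresh:g}"
    return True, "ok"


def expected_dosage(probs: np.ndarray, minor_is_allele_b: bool) -> np.ndarray:
    """Expected minor-allele dose per individual, in [0, 2]; NaN if missing.

    Accepts a single triplet of shape (3,) or an (N, 3) array.
    """
    p = np.atleast_2d(probs)
    if minor_is_allele_b:
        dose = p[:, 1] + 2.0 * p[:, 2]
    else:
        dose = p[:, 1] + 2.0 * p[:, 0]
    return dose if probs.ndim == 2 else dose[0]


def threshold_call(
    probs: np.ndarray, call_thres: float, minor_is_allele_b: bool
) -> np.ndarray:
    """Hard-called minor-allele count (0, 1, 2) per individual.

    The genotype with probability at or above ``call_thres`` is called;
    if no probability reaches the cut-off the genotype is missing (NaN).
    Accepts a (3,) triplet or an (N, 3) array.
    """
    p = np.atleast_2d(probs)
    best = np.nanargmax(np.where(np.isnan(p), -1.0, p), axis=1)
    top = np.take_along_axis(p, best[:, None], axis=1)[:, 0]
    b_copies = best.astype(float)
    count = b_copies if minor_is_allele_b else 2.0 - b_copies
    count = np.where(np.isnan(top) | (top < call_thres), np.nan, count)
    return count if probs.ndim == 2 else count[0]


@dataclass
class BurdenVector:
    """Per-individual regional burden: counts, proportion and weight.

    ``r`` is the (possibly fractional, under expected dosage) minor-allele
    count, ``n`` the number of variants with a usable genotype, ``z`` the
    proportion (NaN where ``n == 0``), ``w = n`` the regression weight, and
    ``excluded`` flags individuals with no usable variant.  ``variants``
    lists (rs_id, maf) pairs of the collapsed variants for logging.
    """

    r: np.ndarray
    n: np.ndarray
    z: np.ndarray
    w: np.ndarray
    excluded: np.ndarray
    variants: list[tuple[str, float]]

    @property
    def n_variants(self) -> int:
        return len(self.variants)


def build_burden(
    region: Region,
    oriented_variants: list[OrientedVariant],
    method: str = "expected",
    call_thres: float = 0.9,
    include_mask: np.ndarray | None = None,
    denominator: str = "alleles",
) -> BurdenVector:
    """Collapse a region's filtered variants into a per-individual burden.

    ``method="expected"`` accumulates expected dosages over non-missing
    triplets; ``method="threshold"`` accumulates hard calls, counting only
    variants whose call reaches ``call_thres``.  ``denominator="alleles"``
    gives ``z = r / (2 n)``; ``"variants"`` gives the literal ``r / n``.
    Individuals outside ``include_mask`` (and those with ``n == 0``) are
    flagged excluded.
    """
    if method not in ("expected", "threshold"):
        raise ValueError(f"unknown method {method!r}")
    if denominator not in ("alleles", "variants"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    if not oriented_variants:
        raise RegionSkipped(f"region {region.name!r}: no qualifying rare variants")

    n_ind = oriented_variants[0].variant.n_individuals
    r = np.zeros(n_ind)
    n = np.zeros(n_ind, dtype=int)
    for ov in oriented_variants:
        if method == "expected":
            dose = expected_dosage(ov.variant.probs, ov.minor_is_allele_b)
        else:
            dose = threshold_call(ov.variant.probs, call_thres, ov.minor_is_allele_b)
        usable = ~np.isnan(dose)
        r[usable] += dose[usable]
        n[usable] += 1

    if include_mask is not None:
        r[~include_mask] = 0.0
        n[~include_mask] = 0

    with np.errstate(invalid="ignore", divide="ignore"):
        denom = 2.0 * n if denominator == "alleles" else n.astype(float)
        z = np.where(n > 0, r / np.where(n > 0, denom, 1.0), np.nan)
    w = n.astype(float)
    excluded = n == 0
    variants = [(ov.variant.rs_id, ov.maf) for ov in oriented_variants]
    return BurdenVector(r=r, n=n, z=z, w=w, excluded=excluded, variants=variants)
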