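"""Genotype handling: additive dosage coding, Hardy–Weinberg testing,
kinship-threshold relative pruning, and single-variant VCF ingestion.

The additive score counts type-2-diabetes risk alleles per person at a
biallelic SNP (reference homozygote = 0, heterozygote = 1, risk homozygote
= 2). Hardy–Weinberg equilibrium is assessed with the 1-df goodness-of-fit
chi-square against expected proportions (1-p)^2 : 2p(1-p) : p^2 (an exact
mid-less test is available as an option). Close relatives flagged by
pairwise genome sharing (0.35 < pi-hat < 0.98) are pruned greedily, dropping
from each flagged pair the member with fewer non-missing weight
measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

__all__ = [
    "GenotypeCounts",
    "additive_code",
    "genotype_counts_from_dosage",
    "hwe_test",
    "prune_relatives",
    "read_variant_vcf",
    "PI_HAT_LOWER",
    "PI_HAT_UPPER",
]

PI_HAT_LOWER = 0.35
PI_HAT_UPPER = 0.98


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts at a biallelic variant (risk allele second)."""

    n_ref_hom: int   # e.g. CC
    n_het: int       # e.g. CT
    n_risk_hom: int  # e.g. TT

    def __post_init__(self) -> None:
        if min(self.n_ref_hom, self.n_het, self.n_risk_hom) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.n_total == 0:
            raise ValueError("no genotyped individuals")

    @property
    def n_total(self) -> int:
        return self.n_ref_hom + self.n_het + self.n_risk_hom

    @property
    def risk_allele_freq(self) -> float:
        return (self.n_het + 2 * self.n_risk_hom) / (2 * self.n_total)


def additive_code(
    genotype: tuple[str, str] | str | None,
    risk_allele: str,
    ref_allele: str | None = None,
) -> float:
    """Count risk alleles in an unordered allele pair; missing propagates.

    Accepts a 2-tuple of allele strings or a 2-character string like "CT".
    Order is irrelevant. An allele outside {ref, risk} raises, naming the
    offending call.
    """
    if genotype is None:
        return float("nan")
    if isinstance(genotype, float) and math.isnan(genotype):
        return float("nan")
    if isinstance(genotype, str):
        if genotype in ("", "./.", "NA"):
            return float("nan")
        alleles = tuple(genotype)
    else:
        alleles = tuple(genotype)
    if len(alleles) != 2:
        raise ValueError(f"genotype {genotype!r} is not an allele pair")
    if any(a is None for a in alleles):
        return float("nan")
    for a in alleles:
        if a != risk_allele and (ref_allele is not None and a != ref_allele):
            raise ValueError(
                f"allele {a!r} is neither reference {ref_allele!r} nor risk {risk_allele!r}"
            )
    return float(sum(1 for a in alleles if a == risk_allele))


def genotype_counts_from_dosage(dosage: Iterable[float]) -> GenotypeCounts:
    d = np.asarray(list(dosage), dtype=float)
    d = d[~np.isnan(d)]
    return GenotypeCounts(
        int(np.sum(d == 0)), int(np.sum(d == 1)), int(np.sum(d == 2))
    )


def hwe_test(counts: GenotypeCounts, method: str = "chi2") -> tuple[float, float]:
    """Hardy–Weinberg goodness-of-fit test; returns ``(statistic, p_value)``.

    ``chi2`` (default): 1-df chi-square of observed genotype counts against
    N * {(1-p)^2, 2p(1-p), p^2} at the estimated allele frequency, no
    continuity correction. ``exact``: conditional exact test enumerating all
    heterozygote counts compatible with the observed allele counts
    (two-sided by summing configurations no more probable than the observed);
    the statistic returned is the observed heterozygote count.
    """
    N = counts.n_total
    p = counts.risk_allele_freq
    if method == "chi2":
        expected = N * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        if np.any(expected == 0):
            raise ValueError("monomorphic variant: an expected genotype count is zero")
        observed = np.array([counts.n_ref_hom, counts.n_het, counts.n_risk_hom], dtype=float)
        chi2 = float(np.sum((observed - expected) ** 2 / expected))
        return chi2, float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        n_rare = counts.n_het + 2 * min(counts.n_ref_hom, counts.n_risk_hom)
        if n_rare == 0 or n_rare == 2 * N:
            raise ValueError("monomorphic variant: exact test undefined")
        probs = _exact_het_probs(N, n_rare)
        obs = counts.n_het
        p_obs = probs.get(obs, 0.0)
        pval = min(1.0, sum(q for q in probs.values() if q <= p_obs * (1 + 1e-12)))
        return float(obs), float(pval)
    raise ValueError("method must be 'chi2' or 'exact'")


def _exact_het_probs(N: int, n_rare: int) -> dict[int, float]:
    """P(heterozygote count | N diploids, n_rare minor alleles) under HWE."""
    lg = math.lgamma

    def logp(h: int) -> float:
        # Levene/Haldane distribution; h-independent factors cancel in the
        # normalization below
        ra = (n_rare - h) // 2           # rare homozygotes
        ca = N - h - ra                  # common homozygotes
        return -lg(h + 1) - lg(ra + 1) - lg(ca + 1) + h * math.log(2)
    hs = [h for h in range(n_rare % 2, n_rare + 1, 2) if N - h - (n_rare - h) // 2 >= 0]
    raw = np.array([logp(h) for h in hs])
    raw -= raw.max()
    w = np.exp(raw)
    w /= w.sum()
    return dict(zip(hs, w))


def prune_relatives(
    pairs: Iterable[tuple[str, str, float]],
    n_weights: Mapping[str, int],
    lower: float = PI_HAT_LOWER,
    upper: float = PI_HAT_UPPER,
) -> set[str]:
    """Resolve the close-relative graph; returns the kept id set.

    Pairs with ``lower < pi_hat < upper`` (strict, matching the published
    window) are flagged; pairs at or above ``upper`` are duplicate-QC domain
    and are ignored here. Flagged pairs are processed in descending pi-hat
    order (ties by id); within a pair still fully present, the member with
    fewer non-missing weight measurements is dropped, ties dropping the
    lexicographically larger id. A final deterministic reclaim pass restores
    any dropped individual whose flagged partners were all themselves
    dropped, so no one is excluded gratuitously. The kept set never contains
    a flagged pair and is maximal.
    """
    pairs = list(pairs)
    for id1, id2, pi in pairs:
        if id1 == id2:
            raise ValueError(f"self-pair {id1!r} in kinship input")
        for i in (id1, id2):
            if i not in n_weights:
                raise ValueError(f"kinship id {i!r} absent from cohort")
        if not 0.0 <= pi <= 1.0:
            raise ValueError(f"pi_hat {pi} outside [0, 1] for pair ({id1}, {id2})")
    flagged = [p for p in pairs if lower < p[2] < upper]
    flagged.sort(key=lambda p: (-p[2], str(p[0]), str(p[1])))
    keep = set(n_weights)
    for id1, id2, _ in flagged:
        if id1 in keep and id2 in keep:
            w1, w2 = n_weights[id1], n_weights[id2]
            if w1 < w2:
                keep.discard(id1)
            elif w2 < w1:
                keep.discard(id2)
            else:
                keep.discard(max(str(id1), str(id2)))
    # reclaim: re-admit (most-measured first, then id) anyone with no
    # remaining flagged partner among the kept
    dropped = sorted(set(n_weights) - keep, key=lambda i: (-n_weights[i], str(i)))
    for cand in dropped:
        if not any(
            (a == cand and b in keep) or (b == cand and a in keep)
            for a, b, _ in flagged
        ):
            keep.add(cand)
    return keep


def read_variant_vcf(path, variant_id: str) -> dict[str, tuple[str, str] | None]:
    """Read one biallelic SNP row from a VCF (v4.x) by its ID.

    Returns per-sample unordered allele pairs keyed by sample name; ``./.``
    (or any missing GT) maps to None. Raises a descriptive error if the
    variant is absent, multiallelic, or its GT fields are malformed.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        rec = None
        for r in vf.fetch() if vf.index is not None else vf:
            if r.id == variant_id:
                rec = r
                break
        if rec is None:
            raise ValueError(f"variant {variant_id!r} not found in {path}")
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(f"variant {variant_id!r} is not biallelic")
        alleles = (rec.ref, rec.alts[0])
        out: dict[str, tuple[str, str] | None] = {}
        for sample, call in rec.samples.items():
            gt = call.get("GT")
            if gt is None or any(a is None for a in gt):
                out[sample] = None
                continue
            if len(gt) != 2 or any(a not in (0, 1) for a in gt):
                raise ValueError(
                    f"malformed GT {gt!r} for sample {sample!r} at {variant_id!r}"
                )
            out[sample] = (alleles[gt[0]], alleles[gt[1]])
        return out
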