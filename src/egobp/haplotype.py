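"""Haplotype frequency estimation, phasing, LD, and regression codings.

The markers of interest are the ACE-gene trio rs4313 (C/T), rs4337 (C/G) and
the intron-16 Alu insertion (I = insertion, N = noninsertion).  Four named
haplotypes span this block:

====  =======
name  alleles
====  =======
hap1  T-G-N
hap2  C-G-N
hap3  T-G-I
hap4  T-C-I
====  =======

Phasing uses the classic Excoffier–Slatkin EM algorithm on unphased
multilocus genotypes: the E-step distributes each individual's genotype over
the diplotypes (haplotype pairs) compatible with it, in proportion to
``f_h1 * f_h2`` (doubled for heterozygous pairs); the M-step re-estimates the
haplotype frequencies from the expected counts.  The observed-data
log-likelihood is non-decreasing across iterations.  Missing genotypes at a
subset of markers simply enlarge the compatible-diplotype set; individuals
missing every marker are excluded.

Pairwise LD is summarised by D, D' (Lewontin) and r-squared computed from
two-locus haplotype frequencies; LD blocks are maximal runs of contiguous
markers whose pairwise D' all clear a threshold (default 0.8).

Generic support covers up to 5 biallelic markers; only the three-marker ACE
block has a named-haplotype namespace.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: marker name -> allowed alleles, in map order for the ACE block 1 trio
ACE_MARKERS = (
    ("rs4313", ("C", "T")),
    ("rs4337", ("C", "G")),
    ("ace_alu", ("I", "N")),
)

#: the four named ACE haplotypes (rs4313-rs4337-Alu)
NAMED_HAPLOTYPES = {
    "hap1": ("T", "G", "N"),
    "hap2": ("C", "G", "N"),
    "hap3": ("T", "G", "I"),
    "hap4": ("T", "C", "I"),
}
HAPLOTYPE_NAMES = {v: k for k, v in NAMED_HAPLOTYPES.items()}
REFERENCE_HAPLOTYPE = "hap1"

MAX_MARKERS = 5


class GenotypeError(ValueError):
    """Raised for malformed or impossible genotype input."""


@dataclass(frozen=True)
class HaplotypeFrequencies:
    frequencies: dict          # haplotype tuple -> frequency
    log_likelihood: float
    iterations: int
    converged: bool
    log_likelihood_path: tuple = ()

    def as_named(self) -> dict:
        """Frequencies keyed by haplotype name where one exists."""
        return {HAPLOTYPE_NAMES.get(h, "-".join(h)): f
                for h, f in self.frequencies.items()}


@dataclass(frozen=True)
class DiplotypePosterior:
    participant_id: object
    diplotypes: tuple          # ((hap_a, hap_b), ...) with hap_a <= hap_b
    posteriors: np.ndarray

    @property
    def best(self):
        """Most probable diplotype; lexicographic tie-break."""
        best_p = self.posteriors.max()
        candidates = [d for d, p in zip(self.diplotypes, self.posteriors)
                      if p >= best_p - 1e-12]
        return min(candidates)

    @property
    def best_posterior(self) -> float:
        return float(self.posteriors.max())


@dataclass(frozen=True)
class LDStats:
    marker_a: str
    marker_b: str
    d: float
    d_prime: float
    r_squared: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.d_prime)


def parse_genotype(value, alleles: Sequence[str], marker: str) -> Optional[frozenset]:
    """Parse an unordered ``"X/Y"`` genotype; None/NaN/"./." mean missing."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", ".", "./.", "NA", "nan"):
        return None
    parts = s.split("/")
    if len(parts) != 2:
        raise GenotypeError(f"{marker}: genotype {value!r} is not of the form X/Y")
    for p in parts:
        if p not in alleles:
            raise GenotypeError(
                f"{marker}: allele {p!r} not in alphabet {tuple(alleles)}")
    return frozenset(parts) if parts[0] != parts[1] else frozenset([parts[0]])


def compatible_diplotypes(genotype: Sequence[Optional[frozenset]],
                          markers: Sequence = ACE_MARKERS) -> list:
    """All unordered haplotype pairs compatible with one multilocus genotype.

    A missing marker contributes every unordered allele pair of its alphabet.
    """
    per_marker = []
    for g, (name, alleles) in zip(genotype, markers):
        if g is None:
            pairs = [(a, b) for a in alleles for b in alleles]
        else:
            al = sorted(g)
            pairs = [(al[0], al[0])] if len(al) == 1 else [(al[0], al[1]), (al[1], al[0])]
        per_marker.append(pairs)
    seen = set()
    for combo in itertools.product(*per_marker):
        h1 = tuple(p[0] for p in combo)
        h2 = tuple(p[1] for p in combo)
        seen.add((h1, h2) if h1 <= h2 else (h2, h1))
    return sorted(seen)


def _parse_table(genotypes: pd.DataFrame, markers) -> list:
    parsed = []
    for row in genotypes.itertuples(index=False):
        pid = row.participant_id
        gt = tuple(parse_genotype(getattr(row, name), alleles, name)
                   for name, alleles in markers)
        parsed.append((pid, gt))
    return parsed


def em_phase(genotypes: pd.DataFrame, tol: float = 1e-8, max_iter: int = 1000,
             markers: Sequence = ACE_MARKERS):
    """Excoffier–Slatkin EM haplotype phasing.

    Parameters
    ----------
    genotypes
        DataFrame with ``participant_id`` plus one ``"X/Y"`` column per
        marker.  Individuals missing every marker are dropped (logged).
    tol
        Convergence threshold on the log-likelihood increment.

    Returns
    -------
    (HaplotypeFrequencies, list[DiplotypePosterior])
    """
    if len(markers) > MAX_MARKERS:
        raise GenotypeError(f"at most {MAX_MARKERS} markers supported")
    parsed = _parse_table(genotypes, markers)
    kept = [(pid, gt) for pid, gt in parsed if any(g is not None for g in gt)]
    n_dropped = len(parsed) - len(kept)
    if n_dropped:
        logger.info("em_phase: excluded %d individuals missing all markers", n_dropped)
    if not kept:
        raise GenotypeError("no individuals with at least one typed marker")

    # group identical genotype patterns for speed
    pattern_index: dict = {}
    pattern_count: list = []
    pattern_ids: list = []
    for pid, gt in kept:
        if gt not in pattern_index:
            pattern_index[gt] = len(pattern_count)
            pattern_count.append(0)
            pattern_ids.append([])
        k = pattern_index[gt]
        pattern_count[k] += 1
        pattern_ids[k].append(pid)
    patterns = list(pattern_index)
    counts = np.asarray(pattern_count, dtype=float)
    diplos = [compatible_diplotypes(gt, markers) for gt in patterns]

    hap_set = sorted({h for dl in diplos for pair in dl for h in pair})
    hap_idx = {h: i for i, h in enumerate(hap_set)}
    n_hap = len(hap_set)
    # per pattern: index arrays and het multiplier
    idx1 = [np.array([hap_idx[a] for a, b in dl]) for dl in diplos]
    idx2 = [np.array([hap_idx[b] for a, b in dl]) for dl in diplos]
    mult = [np.array([2.0 if a != b else 1.0 for a, b in dl]) for dl in diplos]

    freqs = np.full(n_hap, 1.0 / n_hap)
    ll_path = []
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expected = np.zeros(n_hap)
        ll = 0.0
        for k in range(len(patterns)):
            w = mult[k] * freqs[idx1[k]] * freqs[idx2[k]]
            total = w.sum()
            if total <= 0:
                # degenerate: current freqs give this genotype probability 0
                w = mult[k].copy()
                total = w.sum()
                ll += counts[k] * (-np.inf)
            else:
                ll += counts[k] * np.log(total)
            post = w / total
            np.add.at(expected, idx1[k], counts[k] * post)
            np.add.at(expected, idx2[k], counts[k] * post)
        freqs = expected / expected.sum()
        ll_path.append(ll)
        if np.isfinite(ll) and ll - prev_ll < tol and it > 1:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    if not converged:
        logger.warning("em_phase: not converged after %d iterations", it)

    freq_map = {h: float(f) for h, f in zip(hap_set, freqs)}
    result = HaplotypeFrequencies(frequencies=freq_map, log_likelihood=float(prev_ll),
                                  iterations=it, converged=converged,
                                  log_likelihood_path=tuple(ll_path))

    posteriors = []
    for pid, gt in kept:
        k = pattern_index[gt]
        w = mult[k] * freqs[idx1[k]] * freqs[idx2[k]]
        total = w.sum()
        post = w / total if total > 0 else mult[k] / mult[k].sum()
        posteriors.append(DiplotypePosterior(participant_id=pid,
                                             diplotypes=tuple(diplos[k]),
                                             posteriors=post))
    return result, posteriors


def genotype_log_likelihood(genotypes: pd.DataFrame, freqs: Mapping[tuple, float],
                            markers: Sequence = ACE_MARKERS) -> float:
    """Observed-data log-likelihood of unphased genotypes under ``freqs``."""
    parsed = [(pid, gt) for pid, gt in _parse_table(genotypes, markers)
              if any(g is not None for g in gt)]
    ll = 0.0
    for _, gt in parsed:
        total = 0.0
        for h1, h2 in compatible_diplotypes(gt, markers):
            m = 2.0 if h1 != h2 else 1.0
            total += m * freqs.get(h1, 0.0) * freqs.get(h2, 0.0)
        ll += np.log(total) if total > 0 else -np.inf
    return float(ll)


#: VCF record IDs accepted for each marker (rs4646004 is the Alu insertion)
VCF_MARKER_IDS = {"rs4313": "rs4313", "rs4337": "rs4337",
                  "rs4646004": "ace_alu", "ace_alu": "ace_alu"}


def genotypes_from_vcf(path, markers: Sequence = ACE_MARKERS) -> pd.DataFrame:
    """Read unphased genotypes for the three ACE markers from a VCF.

    Records are matched by ID (``rs4313``, ``rs4337``, ``rs4646004`` or
    ``ace_alu``); the Alu insertion is encoded with literal ``N``/``I``
    allele strings.  Unphased ``0/1``-style GT fields are accepted; missing
    calls become missing genotypes.  Returns the same table layout as
    ``genotypes.csv``.
    """
    import pysam

    wanted = {name for name, _ in markers}
    calls: dict = {}
    samples: list = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            marker = VCF_MARKER_IDS.get(rec.id or "")
            if marker is None or marker not in wanted:
                continue
            alleles = rec.alleles
            for sample in samples:
                gt = rec.samples[sample]["GT"]
                if gt is None or any(a is None for a in gt):
                    calls[(sample, marker)] = None
                else:
                    pair = sorted(alleles[a] for a in gt)
                    calls[(sample, marker)] = "/".join(pair)
    missing = wanted - {m for (_, m) in calls}
    if missing:
        raise GenotypeError(f"VCF lacks records for markers: {sorted(missing)}")
    rows = [{"participant_id": s,
             **{m: calls.get((s, m)) for m in (name for name, _ in markers)}}
            for s in samples]
    return pd.DataFrame(rows)


def _two_locus_freqs(freqs: Mapping[tuple, float], i: int, j: int) -> dict:
    out: dict = {}
    for hap, f in freqs.items():
        key = (hap[i], hap[j])
        out[key] = out.get(key, 0.0) + f
    return out


def pairwise_ld(freqs: Mapping[tuple, float], markers: Sequence = ACE_MARKERS,
                pair: tuple = (0, 1)) -> LDStats:
    """D, D' and r-squared for one marker pair from haplotype frequencies.

    The 'A' allele at each locus is the first allele of its alphabet.  A
    monomorphic marker makes LD undefined (NaN fields).
    """
    i, j = pair
    name_a, alleles_a = markers[i]
    name_b, alleles_b = markers[j]
    two = _two_locus_freqs(freqs, i, j)
    p_a = sum(f for (a, _), f in two.items() if a == alleles_a[0])
    p_b = sum(f for (_, b), f in two.items() if b == alleles_b[0])
    if min(p_a, 1 - p_a) <= 0 or min(p_b, 1 - p_b) <= 0:
        return LDStats(name_a, name_b, float("nan"), float("nan"), float("nan"))
    p_ab = two.get((alleles_a[0], alleles_b[0]), 0.0)
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        d_max = 1.0
    d_prime = abs(d) / d_max
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDStats(name_a, name_b, float(d), float(d_prime), float(r2))


def ld_matrix(freqs: Mapping[tuple, float], markers: Sequence = ACE_MARKERS) -> list:
    """LDStats for every marker pair (i < j) in map order."""
    m = len(markers)
    return [pairwise_ld(freqs, markers, (i, j))
            for i in range(m) for j in range(i + 1, m)]


def ld_blocks(ld_stats: Iterable[LDStats], markers: Sequence = ACE_MARKERS,
              d_prime_threshold: float = 0.8) -> list:
    """Greedy left-to-right partition into strong-LD blocks.

    A block extends to the next marker only if *every* pairwise D' within the
    extended block clears the threshold (undefined D' fails).  Returns a list
    of lists of marker indices.
    """
    m = len(markers)
    names = [name for name, _ in markers]
    dp = {}
    for s in ld_stats:
        dp[(names.index(s.marker_a), names.index(s.marker_b))] = s.d_prime
    blocks = []
    current = [0]
    for j in range(1, m):
        ok = all(np.isfinite(dp.get((i, j), np.nan))
                 and dp[(i, j)] >= d_prime_threshold for i in current)
        if ok:
            current.append(j)
        else:
            blocks.append(current)
            current = [j]
    blocks.append(current)
    return blocks


def assign_and_code(posteriors: Sequence[DiplotypePosterior],
                    frequencies: Optional[HaplotypeFrequencies] = None,
                    reference: str = REFERENCE_HAPLOTYPE,
                    mode: str = "dosage") -> pd.DataFrame:
    """Best diplotype per individual plus a regression coding.

    ``mode="dosage"`` (default) emits one 0/1/2 column per named non-reference
    haplotype, counting copies in the best diplotype; the reference haplotype
    (hap1, T-G-N) is the omitted comparison group.  ``mode="categorical"``
    assigns one mutually-exclusive group per individual by rarest-first
    priority: an individual's group is the lowest-frequency named haplotype
    they carry (estimated frequencies; ties by name).
    """
    if reference not in NAMED_HAPLOTYPES:
        raise GenotypeError(f"unknown reference haplotype {reference!r}")
    if mode not in ("dosage", "categorical"):
        raise ValueError(f"unknown coding mode {mode!r}")
    non_ref = [n for n in NAMED_HAPLOTYPES if n != reference]

    if mode == "categorical":
        if frequencies is None:
            raise GenotypeError("categorical coding needs estimated frequencies")
        est = {n: frequencies.frequencies.get(h, 0.0)
               for n, h in NAMED_HAPLOTYPES.items()}
        priority = sorted(NAMED_HAPLOTYPES, key=lambda n: (est[n], n))

    rows = []
    for post in posteriors:
        h1, h2 = post.best
        names = []
        for h in (h1, h2):
            if h not in HAPLOTYPE_NAMES:
                raise GenotypeError(
                    f"participant {post.participant_id}: best diplotype contains "
                    f"unnamed haplotype {'-'.join(h)}")
            names.append(HAPLOTYPE_NAMES[h])
        row = {
            "participant_id": post.participant_id,
            "hap_a": names[0],
            "hap_b": names[1],
            "posterior": post.best_posterior,
        }
        for n in non_ref:
            row[f"dosage_{n}"] = names.count(n)
        if mode == "categorical":
            row["group"] = next(p for p in priority if p in names)
        rows.append(row)
    out = pd.DataFrame(rows)
    constant = [c for c in out.columns if c.startswith("dosage_")
                and out[c].nunique() <= 1]
    if constant:
        logger.warning("assign_and_code: constant design columns %s "
                       "(flagged for exclusion)", constant)
        out.attrs["constant_columns"] = constant
    return out
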