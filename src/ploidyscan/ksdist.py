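"""Synonymous/nonsynonymous divergence (Nei-Gojobori) and Ks mixture fitting.

Per colinear gene pair, coding sequences are codon-aligned through their
protein translation and Ks/Ka are estimated with the Nei-Gojobori (1986)
method: synonymous site fractions from single-step codon neighbors
(normalized so every codon contributes three sites, mutations to stop
codons counted as nonsynonymous), observed differences averaged over all
minimal mutational pathways, and the Jukes-Cantor correction
``d = -(3/4) ln(1 - (4/3) p)`` applied to the synonymous and nonsynonymous
proportions.  Saturated pairs (p >= 3/4) are flagged undefined.

A sample of Ks values is summarized by a Gaussian-kernel density on a fixed
grid and decomposed into the smallest number of Gaussian components whose
least-squares fit to that density reaches the target R-squared.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_CODON_TABLE.stop_codons)
_AA = dict(_CODON_TABLE.forward_table)
_NUCS = "ACGT"


@dataclasses.dataclass(frozen=True)
class KsEstimate:
    """Nei-Gojobori divergence of one aligned gene pair."""

    pair: tuple[str, str]
    ks: float | None  # None when saturated
    ka: float | None
    s_sites: float
    n_sites: float

    @property
    def defined(self) -> bool:
        return self.ks is not None


@dataclasses.dataclass(frozen=True)
class GaussianComponent:
    mean: float
    sd: float
    weight: float


@dataclasses.dataclass
class KsPeakFit:
    """Mixture decomposition of a Ks sample's kernel density."""

    components: list[GaussianComponent]
    r_squared: float
    bandwidth: float
    n_components: int
    principal: int  # index of the heaviest component
    converged: bool
    grid: np.ndarray
    density: np.ndarray

    @property
    def principal_mean(self) -> float:
        return self.components[self.principal].mean


# --------------------------------------------------------------------------
# codon alignment


def _translate(cds: str, name: str) -> str:
    if len(cds) % 3 != 0:
        raise ValueError(f"{name}: CDS length {len(cds)} not divisible by 3")
    prot = str(Seq(cds).translate())
    if "*" in prot:
        raise ValueError(f"{name}: stop codon in CDS")
    if "X" in prot or "J" in prot:
        raise ValueError(f"{name}: untranslatable codon")
    return prot


def align_codons(cds_a: str, cds_b: str, name_a: str = "a", name_b: str = "b"
                 ) -> tuple[list[str], list[str]]:
    """Protein-guided global codon alignment of two coding sequences.

    Returns two equal-length lists of codons where gaps are ``---``; gap
    columns are skipped in site counting downstream.
    """
    prot_a = _translate(cds_a, name_a)
    prot_b = _translate(cds_b, name_b)
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    aln = aligner.align(prot_a, prot_b)[0]
    codons_a: list[str] = []
    codons_b: list[str] = []
    ia = ib = 0
    for col_a, col_b in zip(*aln):
        if col_a == "-":
            codons_a.append("---")
        else:
            codons_a.append(cds_a[3 * ia:3 * ia + 3])
            ia += 1
        if col_b == "-":
            codons_b.append("---")
        else:
            codons_b.append(cds_b[3 * ib:3 * ib + 3])
            ib += 1
    return codons_a, codons_b


# --------------------------------------------------------------------------
# Nei-Gojobori


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon, summing to 3."""
    aa = _AA[codon]
    s = n = 0.0
    for i, nuc in enumerate(codon):
        for base in _NUCS:
            if base == nuc:
                continue
            neighbor = codon[:i] + base + codon[i + 1:]
            if neighbor in _STOPS:
                n += 1.0
            elif _AA[neighbor] == aa:
                s += 1.0
            else:
                n += 1.0
    total = s + n
    return 3.0 * s / total, 3.0 * n / total


def _step_syn(c1: str, c2: str) -> float:
    """1 if the single-nucleotide step c1->c2 preserves the encoded residue.

    Steps between a sense codon and a stop count as nonsynonymous; the
    pathway itself is still traversed (standard NG86 averaging).
    """
    return 1.0 if _AA.get(c1) == _AA.get(c2) else 0.0


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over minimal pathways."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    sd = nd = 0.0
    n_paths = math.factorial(len(diff))
    for order in itertools.permutations(diff):
        cur = c1
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if _step_syn(cur, nxt):
                sd += 1.0 / n_paths
            else:
                nd += 1.0 / n_paths
            cur = nxt
    return sd, nd


def nei_gojobori(codons_a: Sequence[str], codons_b: Sequence[str],
                 pair: tuple[str, str] = ("a", "b")) -> KsEstimate:
    """Nei-Gojobori Ks/Ka from an aligned codon pair (gap columns skipped)."""
    s1 = n1 = s2 = n2 = sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        if "-" in ca or "-" in cb:
            continue
        if ca in _STOPS or cb in _STOPS:
            raise ValueError(f"stop codon in alignment of pair {pair}")
        xa, ya = _codon_sites(ca)
        xb, yb = _codon_sites(cb)
        s1 += xa
        n1 += ya
        s2 += xb
        n2 += yb
        d_s, d_n = _pair_differences(ca, cb)
        sd += d_s
        nd += d_n
    s_sites = (s1 + s2) / 2.0
    n_sites = (n1 + n2) / 2.0
    if s_sites == 0 or n_sites == 0:
        raise ValueError(f"degenerate alignment for pair {pair}: no countable sites")
    ps = sd / s_sites
    pn = nd / n_sites

    def jc(p: float) -> float | None:
        if p >= 0.75:
            return None  # saturated
        return -0.75 * math.log1p(-4.0 * p / 3.0)

    return KsEstimate(pair=pair, ks=jc(ps), ka=jc(pn), s_sites=s_sites, n_sites=n_sites)


def pair_ks(cds_a: str, cds_b: str, name_a: str = "a", name_b: str = "b") -> KsEstimate:
    """Convenience: align two CDS and estimate Ks/Ka."""
    codons_a, codons_b = align_codons(cds_a, cds_b, name_a, name_b)
    return nei_gojobori(codons_a, codons_b, (name_a, name_b))


# --------------------------------------------------------------------------
# mixture fitting


def kernel_density(values: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian-kernel density of ``values`` evaluated on ``grid``."""
    z = (grid[:, None] - values[None, :]) / bandwidth
    return np.exp(-0.5 * z * z).sum(axis=1) / (values.size * bandwidth * math.sqrt(2 * math.pi))


def _mixture(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x)
    for i in range(0, len(params), 3):
        a, m, s = params[i:i + 3]
        y = y + a * np.exp(-0.5 * ((x - m) / s) ** 2)
    return y


def fit_ks_distribution(ks_values: Sequence[float], bandwidth: float = 0.05,
                        r2_min: float = 0.95, max_components: int = 4,
                        grid_range: tuple[float, float] = (0.0, 3.0),
                        grid_points: int = 300, min_n: int = 50) -> KsPeakFit:
    """Decompose a Ks sample into the smallest adequate Gaussian mixture.

    The kernel density (fixed ``bandwidth``) on an evenly spaced grid is fit
    by least squares with 1..``max_components`` Gaussians; the smallest
    component count reaching ``r2_min`` is returned.  When the target is
    unreachable the best fit is returned with ``converged=False``.  Values
    beyond the grid (Ks > 3 by default) are discarded as saturated noise.
    """
    vals = np.asarray([v for v in ks_values if v is not None and np.isfinite(v)], float)
    vals = vals[(vals >= grid_range[0]) & (vals <= grid_range[1])]
    if vals.size < min_n:
        raise ValueError(f"need >= {min_n} finite Ks values, got {vals.size}")
    grid = np.linspace(*grid_range, grid_points)
    dens = kernel_density(vals, grid, bandwidth)
    ss_tot = float(((dens - dens.mean()) ** 2).sum())

    # candidate component centers from density peaks, by prominence
    peak_idx, props = find_peaks(dens, prominence=1e-3 * dens.max())
    order = np.argsort(props["prominences"])[::-1]
    centers = list(grid[peak_idx[order]])

    best_fit: tuple[float, np.ndarray] | None = None
    for n_comp in range(1, max_components + 1):
        init = []
        lo, hi = [], []
        for i in range(n_comp):
            m0 = centers[i] if i < len(centers) else grid_range[0] + (i + 0.5) * (
                grid_range[1] - grid_range[0]) / n_comp
            a0 = float(np.interp(m0, grid, dens))
            init += [max(a0, 1e-3), m0, 2.0 * bandwidth]
            lo += [0.0, grid_range[0], bandwidth / 4.0]
            hi += [np.inf, grid_range[1], grid_range[1] - grid_range[0]]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(_mixture, grid, dens, p0=init,
                                    bounds=(lo, hi), maxfev=20000)
        except RuntimeError:
            continue
        resid = dens - _mixture(grid, *popt)
        r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
        if best_fit is None or r2 > best_fit[0]:
            best_fit = (r2, popt)
        if r2 >= r2_min:
            return _make_fit(popt, r2, bandwidth, grid, dens, converged=True)

    if best_fit is None:
        raise RuntimeError("mixture fitting failed at every component count")
    r2, popt = best_fit
    return _make_fit(popt, r2, bandwidth, grid, dens, converged=False)


def _make_fit(popt: np.ndarray, r2: float, bandwidth: float, grid: np.ndarray,
              dens: np.ndarray, converged: bool) -> KsPeakFit:
    comps = []
    for i in range(0, len(popt), 3):
        a, m, s = popt[i:i + 3]
        comps.append((float(m), float(s), float(a * s * math.sqrt(2 * math.pi))))
    total_w = sum(c[2] for c in comps) or 1.0
    comps.sort(key=lambda c: c[0])
    components = [GaussianComponent(m, s, w / total_w) for m, s, w in comps]
    principal = max(range(len(components)), key=lambda i: components[i].weight)
    return KsPeakFit(components=components, r_squared=r2, bandwidth=bandwidth,
                     n_components=len(components), principal=principal,
                     converged=converged, grid=grid, density=dens)


def block_median_ks(estimates: Sequence[KsEstimate]) -> float | None:
    """Median of the finite Ks values of a block's gene pairs.

    Even counts take the mean of the central two; returns ``None`` (block
    flagged saturated) when no pair has a defined Ks.
    """
    finite = sorted(e.ks for e in estimates if e.defined)
    if not finite:
        return None
    return float(np.median(finite))
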