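"""Minimal diploid genetics: neutral loci for isolation-by-distance and one
selected locus whose effect acts on mortality or on fecundity.

Genotypes are allele-count vectors in {0, 1, 2} of length L; locus 0 is the
selected locus, loci 1..L-1 are unlinked neutral loci with symmetric
per-transmission mutation.

The selection coefficient ``s`` is defined per *time step*: the allele's
frequency changes on average by a factor 1 + h*s per step while rare at the
equilibrium density.  Mortality-based selection multiplies survival by
1 + k*s/2 for k copies (additive case h = 1/2); fecundity-based selection
sets f_k(u) = (1 + f(u))*(1 + k*s) - 1.  Both give the identical per-capita
allelic growth rate

    G(u) = (1 - mu_1(u)) * (1 + (f_0(u) + f_1(u))/2) - 1

at every density (the fecundity term is averaged because a heterozygous
parent transmits the focal allele only half the time), with G(1) = s/2.
After fixation, though, the two modes settle at different densities:
u* = 1 + s*(1 + 1/f0) for mortality-based and 1 + 2s*(1 + 1/f0) for
fecundity-based selection (Beverton-Holt mortality regulation with a = f),
so a fecundity sweep raises the equilibrium density roughly twice as much.

This per-step ``s`` is not interchangeable with the per-generation s of
Wright-Fisher formulas; no establishment-probability claims are made here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regulation import RegulationModel

__all__ = [
    "SelectionModel",
    "survival_factor",
    "fecundity_with_selection",
    "allelic_growth_rate",
    "post_fixation_equilibrium",
    "inherit",
    "clone",
    "genetic_distance_matrix",
]


@dataclass(frozen=True)
class SelectionModel:
    """Selection on the focal locus plus neutral-locus mutation settings.

    s : per-tick selection coefficient (rare-allele growth convention).
    h : dominance (0.5 = additive, the default, reproducing the s/2-per-copy
        survival form exactly).
    mode : "mortality", "fecundity", or "none".
    mu_neutral : per-transmitted-allele flip probability at neutral loci.
    """

    s: float = 0.0
    h: float = 0.5
    mode: str = "none"
    mu_neutral: float = 0.0

    def __post_init__(self):
        if self.mode not in ("mortality", "fecundity", "none"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if not 0.0 <= self.mu_neutral < 1.0:
            raise ValueError("mu_neutral must be in [0, 1)")

    def _factor(self, k, per_copy: float):
        """Dominance-general multiplier: 1, 1 + 2*h*x, 1 + 2*x for k=0,1,2
        where x is the per-homozygote half-effect."""
        k = np.asarray(k)
        return 1.0 + per_copy * np.where(k == 1, 2.0 * self.h, k.astype(float))

    def survival_factor(self, k):
        """Survival multiplier for k copies (mortality mode): 1 + k*s/2 when
        additive.  The engine clips the resulting probability at 1 (with a
        warning) if the base survival is too close to 1 for the boost."""
        k = np.asarray(k)
        out = self._factor(k, self.s / 2.0) if self.mode == "mortality" else np.ones(k.shape)
        return out if out.ndim else float(out)

    def fecundity_factor_args(self, k):
        """The (1 + k*s)-style multiplier entering f_k = (1+f)(1+k*s) - 1."""
        k = np.asarray(k)
        out = self._factor(k, self.s) if self.mode == "fecundity" else np.ones(k.shape)
        return out if out.ndim else float(out)

    def fecundity_with_selection(self, k, f_u):
        """Mean offspring for k copies: (1 + f(u)) * (1 + k*s) - 1."""
        f_u = np.asarray(f_u, dtype=float)
        if self.mode != "fecundity":
            out = np.broadcast_to(f_u, np.broadcast(f_u, np.asarray(k)).shape)
            return out if out.ndim else float(out)
        out = (1.0 + f_u) * self.fecundity_factor_args(k) - 1.0
        if np.any(out < 0):
            raise ValueError("fecundity with selection went negative: s too strongly deleterious")
        return out if np.ndim(out) else float(out)


def survival_factor(selection: SelectionModel, k):
    return selection.survival_factor(k)


def fecundity_with_selection(selection: SelectionModel, k, f_u):
    return selection.fecundity_with_selection(k, f_u)


def allelic_growth_rate(regulation: RegulationModel, selection: SelectionModel, u):
    """Per-capita growth rate G(u) of the number of focal alleles while rare.

    G(u) = (1 - mu_1(u)) (1 + (f_0(u) + f_1(u))/2) - 1 where index k marks
    carriers of k copies.  Identical for mortality- and fecundity-based
    selection at every u; equals F(u) when s = 0, and s/2 at u = 1.
    """
    u = np.asarray(u, dtype=float)
    f0 = regulation.fecundity(u)
    mu = regulation.mortality(u)
    if selection.mode == "mortality":
        surv1 = (1.0 - mu) * selection.survival_factor(1)
        f1 = f0
    elif selection.mode == "fecundity":
        surv1 = 1.0 - mu
        f1 = selection.fecundity_with_selection(np.ones_like(u, dtype=int), f0)
    else:
        surv1, f1 = 1.0 - mu, f0
    out = surv1 * (1.0 + (np.asarray(f0) + np.asarray(f1)) / 2.0) - 1.0
    return out if np.ndim(out) else float(out)


def post_fixation_equilibrium(selection: SelectionModel, f0: float) -> float:
    """Scaled equilibrium density u* after the beneficial allele fixes, for
    Beverton-Holt mortality regulation with a = f = ``f0`` (additive h=1/2).

    Mortality-based selection: u* = 1 + s (1 + 1/f0); fecundity-based:
    u* = 1 + 2 s (1 + 1/f0) — about twice the increase.
    """
    if selection.mode == "mortality":
        return 1.0 + selection.s * (1.0 + 1.0 / f0)
    if selection.mode == "fecundity":
        return 1.0 + 2.0 * selection.s * (1.0 + 1.0 / f0)
    if selection.mode == "none":
        return 1.0
    raise ValueError(f"unsupported selection mode {selection.mode!r}")


# ---------------------------------------------------------------------------
# transmission


def inherit(parent_a, parent_b, rng: np.random.Generator, mu_neutral: float = 0.0):
    """Mendelian transmission with free recombination.

    ``parent_a`` and ``parent_b`` are (n, L) allele-count arrays (rows are
    matings); each parent transmits one allele per locus (probability k/2 of
    transmitting the focal allele), then transmitted alleles at the
    *neutral* loci (1..L-1) flip with probability ``mu_neutral`` each.
    """
    a = np.atleast_2d(np.asarray(parent_a, dtype=np.int8))
    b = np.atleast_2d(np.asarray(parent_b, dtype=np.int8))
    if a.shape != b.shape:
        raise ValueError(f"genotype length mismatch: {a.shape} vs {b.shape}")
    ta = (rng.random(a.shape) < a / 2.0).astype(np.int8)
    tb = (rng.random(b.shape) < b / 2.0).astype(np.int8)
    if mu_neutral > 0.0 and a.shape[1] > 1:
        flip_a = rng.random(a.shape) < mu_neutral
        flip_b = rng.random(b.shape) < mu_neutral
        flip_a[:, 0] = False  # selected locus does not mutate
        flip_b[:, 0] = False
        ta = np.where(flip_a, 1 - ta, ta).astype(np.int8)
        tb = np.where(flip_b, 1 - tb, tb).astype(np.int8)
    return ta + tb


def clone(parent, rng: np.random.Generator, mu_neutral: float = 0.0):
    """Asexual transmission: copy the genotype, flipping each of the two
    alleles at each neutral locus with probability ``mu_neutral``."""
    g = np.atleast_2d(np.asarray(parent, dtype=np.int8))
    if mu_neutral <= 0.0 or g.shape[1] < 2:
        return g.copy()
    a1 = (g >= 1).astype(np.int8)
    a2 = (g == 2).astype(np.int8)
    for hap in (a1, a2):
        flip = rng.random(g.shape) < mu_neutral
        flip[:, 0] = False  # selected locus does not mutate
        hap ^= flip.astype(np.int8)
    return a1 + a2


def genetic_distance_matrix(genotypes):
    """Pairwise genetic distance: mean over *neutral* loci of |k_i - k_j| / 2
    (the proportion of allele differences).  Symmetric with zero diagonal."""
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2:
        raise ValueError("need >= 2 genotyped individuals")
    if g.shape[1] < 2:
        raise ValueError("no neutral loci present (need L >= 2)")
    neutral = g[:, 1:]
    # mean_l |ki - kj|/2, computed per locus to stay exact
    n, L = neutral.shape
    out = np.zeros((n, n))
    for l in range(L):
        out += np.abs(neutral[:, l][:, None] - neutral[:, l][None, :])
    return out / (2.0 * L)
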