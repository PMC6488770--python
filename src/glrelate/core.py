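"""Emission model for pairwise relatedness from genotype likelihoods.

A pair of diploid individuals (a, b) carries four gene copies
``a1, a2, b1, b2`` at each biallelic site.  Ignoring parental origin, the
possible identity-by-descent (IBD) configurations of those four copies
collapse into nine condensed states; their genome-wide frequencies are the
condensed Jacquard coefficients ``J1..J9``.

This module provides, for each condensed state ``m`` and population allele
frequency ``f``:

* the prior distribution of ordered genotype pairs ``P(G_a, G_b | f, m)``,
  derived by summing over allele assignments to the IBD blocks of state
  ``m`` (each block draws a single allele from the population, Bernoulli
  with success probability ``f``);
* the per-site emission ``P(D_a, D_b | m, f)`` obtained by integrating the
  genotype-pair prior against the two individuals' genotype likelihoods;
* the composite log-likelihood of a Jacquard vector over unlinked sites.

Genotypes are coded 0/1/2 = copies of the allele whose frequency is ``f``
(the second allele listed in GL files).  Genotype likelihoods are relative:
any per-site positive rescaling changes the log-likelihood only by an
additive constant.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "STATE_PARTITIONS",
    "N_STATES",
    "DegenerateSiteError",
    "genotype_pair_prior",
    "site_emissions",
    "pair_loglikelihood",
    "normalize_gl",
    "validate_jacquard",
]

#: Set partitions of the four gene copies (0=a1, 1=a2, 2=b1, 3=b2) into IBD
#: blocks, in the canonical condensed-state order J1..J9.  Copies in the same
#: block are IBD and therefore carry the same allele; distinct blocks draw
#: alleles independently from the population.
STATE_PARTITIONS: tuple[tuple[tuple[int, ...], ...], ...] = (
    ((0, 1, 2, 3),),                # J1: all four copies IBD
    ((0, 1), (2, 3)),               # J2: both inbred, not related
    ((0, 1, 2), (3,)),              # J3: a inbred, one of b's copies IBD with a
    ((0, 1), (2,), (3,)),           # J4: a inbred only
    ((0, 2, 3), (1,)),              # J5: b inbred, one of a's copies IBD with b
    ((2, 3), (0,), (1,)),           # J6: b inbred only
    ((0, 2), (1, 3)),               # J7: two cross pairs IBD (k2)
    ((0, 2), (1,), (3,)),           # J8: one cross pair IBD (k1)
    ((0,), (1,), (2,), (3,)),       # J9: no copies IBD (k0)
)

N_STATES = len(STATE_PARTITIONS)


class DegenerateSiteError(ValueError):
    """A site contributes zero likelihood mass under every permitted state."""

    def __init__(self, site_index: int, message: str | None = None):
        self.site_index = site_index
        super().__init__(message or f"degenerate site at index {site_index}")


def _check_frequencies(f: np.ndarray) -> None:
    if f.size and (np.min(f) <= 0.0 or np.max(f) >= 1.0):
        bad = int(np.argmax((f <= 0.0) | (f >= 1.0)))
        raise ValueError(
            f"allele frequency must lie strictly in (0, 1); offending value "
            f"{f.flat[bad]!r} at position {bad}"
        )


def genotype_pair_prior(f) -> np.ndarray:
    """Genotype-pair prior ``P(G_a, G_b | f, m)`` for all nine condensed states.

    Parameters
    ----------
    f
        Population frequency of the counted allele; scalar or array of
        shape ``(L,)``, each value strictly inside ``(0, 1)``.

    Returns
    -------
    ndarray
        Shape ``(9, 3, 3)`` for scalar input or ``(L, 9, 3, 3)`` otherwise;
        entry ``[m, g, h]`` is the probability that individual a carries
        genotype ``g`` and individual b genotype ``h`` given condensed state
        ``m`` (0-based: state ``m+1``).  Each ``3x3`` slice sums to one.
    """
    f_arr = np.asarray(f, dtype=float)
    scalar = f_arr.ndim == 0
    f_arr = np.atleast_1d(f_arr)
    _check_frequencies(f_arr)
    q = 1.0 - f_arr
    out = np.zeros((f_arr.shape[0], N_STATES, 3, 3))
    for m, partition in enumerate(STATE_PARTITIONS):
        k = len(partition)
        for assignment in itertools.product((0, 1), repeat=k):
            allele = np.empty(4, dtype=int)
            for block, a in zip(partition, assignment):
                for copy in block:
                    allele[copy] = a
            g, h = allele[0] + allele[1], allele[2] + allele[3]
            n_derived = sum(assignment)
            out[:, m, g, h] += f_arr**n_derived * q ** (k - n_derived)
    return out[0] if scalar else out


def site_emissions(gl_a, gl_b, f) -> np.ndarray:
    """Per-site emissions ``P(D_a, D_b | m, f)`` for all nine states.

    Integrates the genotype-pair prior against the two genotype-likelihood
    tables: ``e[l, m] = sum_{g,h} gl_a[l,g] * gl_b[l,h] * P(g, h | f_l, m)``.

    Parameters
    ----------
    gl_a, gl_b
        Genotype likelihoods, shape ``(L, 3)`` (or ``(3,)`` for one site),
        on a linear scale; per-site scaling is arbitrary.
    f
        Allele frequencies, shape ``(L,)`` (or scalar).

    Returns
    -------
    ndarray of shape ``(L, 9)`` (or ``(9,)``), on the input GL scale.

    Raises
    ------
    DegenerateSiteError
        If some site has an all-zero GL row for either individual.
    """
    a = np.atleast_2d(np.asarray(gl_a, dtype=float))
    b = np.atleast_2d(np.asarray(gl_b, dtype=float))
    single = np.asarray(gl_a).ndim == 1
    if a.shape != b.shape or a.shape[1] != 3:
        raise ValueError(f"GL tables must share shape (L, 3); got {a.shape} and {b.shape}")
    if np.min(a) < 0 or np.min(b) < 0:
        raise ValueError("genotype likelihoods must be non-negative")
    for name, tab in (("a", a), ("b", b)):
        row_max = tab.max(axis=1)
        if np.any(row_max == 0):
            raise DegenerateSiteError(
                int(np.argmax(row_max == 0)),
                f"all-zero GL row for individual {name} "
                f"at site {int(np.argmax(row_max == 0))}",
            )
    prior = genotype_pair_prior(np.atleast_1d(np.asarray(f, dtype=float)))
    e = np.einsum("lmgh,lg,lh->lm", prior, a, b, optimize=True)
    return e[0] if single else e


def pair_loglikelihood(j: np.ndarray, emissions: np.ndarray) -> float:
    """Composite log-likelihood ``sum_l log(sum_m J_m e[l, m])``.

    Sites are treated as independent; under linkage this is a composite
    likelihood whose maximizer remains consistent.

    Raises
    ------
    DegenerateSiteError
        If some site has zero total emission under the given ``j``.
    """
    j = validate_jacquard(j)
    e = np.atleast_2d(np.asarray(emissions, dtype=float))
    per_site = e @ j
    if np.any(per_site <= 0.0):
        raise DegenerateSiteError(int(np.argmax(per_site <= 0.0)))
    return float(np.log(per_site).sum())


def normalize_gl(gl: np.ndarray) -> np.ndarray:
    """Rescale each GL row to maximum 1 (likelihoods are relative)."""
    gl = np.atleast_2d(np.asarray(gl, dtype=float))
    row_max = gl.max(axis=1, keepdims=True)
    safe = np.where(row_max > 0, row_max, 1.0)
    return gl / safe


def validate_jacquard(j, tol: float = 1e-8) -> np.ndarray:
    """Check that ``j`` is a 9-vector on the probability simplex."""
    j = np.asarray(j, dtype=float)
    if j.shape != (N_STATES,):
        raise ValueError(f"Jacquard vector must have shape (9,); got {j.shape}")
    if np.min(j) < -tol or np.max(j) > 1 + tol:
        raise ValueError("Jacquard coefficients must lie in [0, 1]")
    if abs(j.sum() - 1.0) > tol:
        raise ValueError(f"Jacquard coefficients must sum to 1; got {j.sum()!r}")
    return np.clip(j, 0.0, 1.0)
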