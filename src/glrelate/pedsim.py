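"""Pedigree gene-dropping simulation and exact identity coefficients.

The simulator emulates the validation setup for genotype-likelihood-based
relatedness estimation:

1. draw unlinked biallelic site frequencies from Uniform(maf, 1 - maf)
   (the MAF filter applied at the source rather than by rejection);
2. give pedigree founders Hardy-Weinberg genotypes (two independent
   Bernoulli(f) draws per site) with uniquely labelled alleles;
3. drop genes down the pedigree — each child inherits, per site
   independently, one uniformly chosen allele from each parent — keeping
   the founder-allele labels so that IBD states are known exactly;
4. generate sequencing reads per site per individual with Poisson(depth)
   coverage and a symmetric per-base error rate, and convert the reads to
   genotype likelihoods.

No linkage disequilibrium, recombination map, mutation or sex chromosomes
are modelled; all sites are independent autosomal SNVs.

``expected_jacquard`` computes the exact condensed identity coefficients
for any pair by enumerating every transmission pattern in the pedigree (two
binary meiosis choices per non-founder per site), which the gene-dropping
proportions converge to.  Three built-in scenario pedigrees cover an
outbred first-cousin pair and two inbred variants (one and both cousins
inbred).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .core import N_STATES, normalize_gl

__all__ = [
    "Pedigree",
    "SimParams",
    "GenomeSet",
    "sample_frequencies",
    "gene_drop",
    "simulate_gls",
    "expected_jacquard",
    "ibd_state_counts",
    "scenario_pedigree",
    "simulate_scenario",
]


@dataclass
class SimParams:
    """Sequencing-simulation settings.

    n_sites
        Number of unlinked biallelic sites.
    depth
        Mean per-site coverage (Poisson parameter), reads.
    error
        Symmetric per-base error probability.
    maf
        Minor-allele-frequency floor; site frequencies are drawn from
        Uniform(maf, 1 - maf).
    seed
        Seeds every random draw.
    """

    n_sites: int = 10_000
    depth: float = 4.0
    error: float = 0.001
    maf: float = 0.1
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if not 0.0 <= self.error < 0.5:
            raise ValueError("error must lie in [0, 0.5)")
        if not 0.0 < self.maf < 0.5:
            raise ValueError("maf must lie in (0, 0.5)")


class Pedigree:
    """A pedigree of diploid individuals given as (child, father, mother) trios.

    Founders have no parents; every non-founder has two distinct parents
    appearing earlier in the order (no cycles, no selfing).
    """

    def __init__(self, trios: list[tuple[str, str | None, str | None]]):
        self.ids: list[str] = []
        self.parents: dict[str, tuple[str, str] | None] = {}
        for child, father, mother in trios:
            if child in self.parents:
                raise ValueError(f"duplicate individual {child!r}")
            if (father is None) != (mother is None):
                raise ValueError(f"{child!r} must have zero or two parents")
            if father is None:
                self.parents[child] = None
            else:
                if father == mother:
                    raise ValueError(f"selfing not supported ({child!r})")
                for p in (father, mother):
                    if p not in self.parents:
                        raise ValueError(
                            f"parent {p!r} of {child!r} not defined earlier "
                            "(cyclic or out-of-order pedigree)"
                        )
                self.parents[child] = (father, mother)
            self.ids.append(child)

    @property
    def founders(self) -> list[str]:
        return [i for i in self.ids if self.parents[i] is None]

    @property
    def nonfounders(self) -> list[str]:
        return [i for i in self.ids if self.parents[i] is not None]

    def ancestors(self, individual: str) -> set[str]:
        """All strict ancestors of ``individual``."""
        out: set[str] = set()
        stack = [individual]
        while stack:
            pp = self.parents[stack.pop()]
            if pp is not None:
                for p in pp:
                    if p not in out:
                        out.add(p)
                        stack.append(p)
        return out

    @classmethod
    def from_trio_file(cls, path) -> "Pedigree":
        """Read a tab-separated trio file: header, then id, father, mother.

        ``0`` (or an empty field) in the parent columns marks a founder,
        following the PLINK-fam trio convention without sex/phenotype.
        """
        trios: list[tuple[str, str | None, str | None]] = []
        with open(path) as fh:
            header = fh.readline()
            if not header.strip():
                raise ValueError(f"{path}: empty pedigree file")
            for line_no, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(f"{path}:{line_no}: expected 3 columns, got {len(parts)}")
                child, father, mother = parts
                father = None if father in ("0", "") else father
                mother = None if mother in ("0", "") else mother
                trios.append((child, father, mother))
        return cls(trios)

    def __len__(self) -> int:
        return len(self.ids)

    def __repr__(self) -> str:
        return f"Pedigree({len(self.founders)} founders, {len(self.nonfounders)} non-founders)"


@dataclass
class GenomeSet:
    """Simulated diploid genomes with founder-allele bookkeeping.

    ``alleles[i]`` is an (L, 2) 0/1 matrix of allelic types; ``labels[i]``
    an (L, 2) integer matrix of founder-allele labels (two copies of the
    same label are IBD).  Genotypes are allele-1 counts.
    """

    alleles: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]
    freqs: np.ndarray = field(repr=False, default=None)

    def genotypes(self, individual: str) -> np.ndarray:
        return self.alleles[individual].sum(axis=1)


def sample_frequencies(n_sites: int, maf: float, seed) -> np.ndarray:
    """Draw site frequencies uniformly on (maf, 1 - maf)."""
    if not 0.0 < maf < 0.5:
        raise ValueError("maf must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    return rng.uniform(maf, 1.0 - maf, size=n_sites)


def gene_drop(ped: Pedigree, freqs: np.ndarray, seed) -> GenomeSet:
    """Drop genes down the pedigree at every site independently.

    Founders receive Hardy-Weinberg genotypes (two Bernoulli(f) draws);
    every non-founder inherits one uniformly chosen allele from each
    parent.  Founder-allele labels ride along for exact IBD tracking.
    """
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    n_sites = freqs.shape[0]
    alleles: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    next_label = 0
    for ind in ped.ids:
        parents = ped.parents[ind]
        if parents is None:
            alleles[ind] = (rng.random((n_sites, 2)) < freqs[:, None]).astype(np.int8)
            labels[ind] = np.full((n_sites, 2), [next_label, next_label + 1], dtype=np.int32)
            next_label += 2
        else:
            a = np.empty((n_sites, 2), dtype=np.int8)
            lab = np.empty((n_sites, 2), dtype=np.int32)
            for k, parent in enumerate(parents):
                pick = rng.integers(0, 2, size=n_sites)
                rows = np.arange(n_sites)
                a[:, k] = alleles[parent][rows, pick]
                lab[:, k] = labels[parent][rows, pick]
            alleles[ind] = a
            labels[ind] = lab
    return GenomeSet(alleles=alleles, labels=labels, freqs=freqs)


def simulate_gls(
    genomes: GenomeSet,
    params: SimParams,
    individuals: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Sequencing reads and genotype likelihoods for the given individuals.

    Per site per individual the read count is Poisson(depth); each read
    samples one of the two carried alleles uniformly and is flipped with
    probability ``error``.  With ``k`` reads of which ``n1`` show allele 1,
    the likelihood of genotype ``g`` is ``p_g^n1 (1 - p_g)^(k - n1)`` where
    ``p_g = (g/2)(1 - e) + (1 - g/2) e``; zero reads give a flat row.
    Rows are max-normalized (likelihood scale is arbitrary).
    """
    rng = np.random.default_rng(params.seed)
    individuals = individuals if individuals is not None else list(genomes.alleles)
    e = params.error
    p_read_alt = np.array([e, 0.5, 1.0 - e])  # P(read shows allele 1 | genotype)
    out: dict[str, np.ndarray] = {}
    for ind in individuals:
        geno = genomes.genotypes(ind)
        n_sites = geno.shape[0]
        depth = rng.poisson(params.depth, size=n_sites)
        n_alt = rng.binomial(depth, p_read_alt[geno])
        n_ref = depth - n_alt
        # n * log(p) with the convention 0 * log(0) = 0 (error-free reads
        # make some genotypes impossible: log-likelihood -inf, not nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_alt = np.log(p_read_alt)[None, :]
            log_ref = np.log1p(-p_read_alt)[None, :]
            loggl = np.where(n_alt[:, None] == 0, 0.0, n_alt[:, None] * log_alt) + np.where(
                n_ref[:, None] == 0, 0.0, n_ref[:, None] * log_ref
            )
        loggl = np.where(depth[:, None] == 0, 0.0, loggl)
        loggl -= loggl.max(axis=1, keepdims=True)
        gl = np.exp(loggl)
        gl[depth == 0] = 1.0
        out[ind] = normalize_gl(gl)
    return out


# --- exact condensed identity coefficients -------------------------------

def _condensed_state(labels: tuple[int, int, int, int]) -> int:
    """Map founder-allele labels of (a1, a2, b1, b2) to a condensed state.

    Returns the 0-based index of the condensed Jacquard state implied by
    the equality partition of the four labels.
    """
    a1, a2, b1, b2 = labels
    fa = a1 == a2
    fb = b1 == b2
    if fa and fb:
        return 0 if a1 == b1 else 1          # J1 / J2
    if fa:
        return 2 if a1 in (b1, b2) else 3    # J3 / J4
    if fb:
        return 4 if b1 in (a1, a2) else 5    # J5 / J6
    cross = sum(x == y for x in (a1, a2) for y in (b1, b2))
    return {2: 6, 1: 7, 0: 8}[cross]         # J7 / J8 / J9


def expected_jacquard(
    ped: Pedigree,
    a: str,
    b: str,
    max_meioses: int = 20,
) -> np.ndarray:
    """Exact condensed identity coefficients for a pair, by enumeration.

    Every non-founder ancestor (or member) of the pair contributes two
    binary meiosis choices per site; enumerating all ``4^n`` transmission
    patterns and classifying the resulting label partition of
    ``(a1, a2, b1, b2)`` yields the exact state probabilities.

    Raises
    ------
    ValueError
        If the relevant pedigree exceeds ``max_meioses`` meioses (default
        20, i.e. 10 non-founders, ~1M patterns); use gene-drop Monte Carlo
        (`gene_drop` + `ibd_state_counts`) for larger pedigrees.
    """
    for ind in (a, b):
        if ind not in ped.parents:
            raise ValueError(f"individual {ind!r} not in pedigree")
    relevant = ({a, b} | ped.ancestors(a) | ped.ancestors(b))
    nonfounders = [i for i in ped.ids if ped.parents[i] is not None and i in relevant]
    n = len(nonfounders)
    if 2 * n > max_meioses:
        raise ValueError(
            f"pedigree needs {2 * n} meioses (> budget {max_meioses}); "
            "use Monte-Carlo gene dropping instead"
        )
    founder_labels: dict[str, tuple[int, int]] = {}
    next_label = 0
    for ind in ped.ids:
        if ped.parents[ind] is None:
            founder_labels[ind] = (next_label, next_label + 1)
            next_label += 2
    counts = np.zeros(N_STATES)
    for choices in itertools.product((0, 1), repeat=2 * n):
        labels: dict[str, tuple[int, int]] = dict(founder_labels)
        for k, ind in enumerate(nonfounders):
            father, mother = ped.parents[ind]
            labels[ind] = (
                labels[father][choices[2 * k]],
                labels[mother][choices[2 * k + 1]],
            )
        counts[_condensed_state(labels[a] + labels[b])] += 1.0
    return counts / counts.sum()


def ibd_state_counts(genomes: GenomeSet, a: str, b: str) -> np.ndarray:
    """Realized condensed-state proportions across sites of a gene drop."""
    la, lb = genomes.labels[a], genomes.labels[b]
    a1, a2, b1, b2 = la[:, 0], la[:, 1], lb[:, 0], lb[:, 1]
    fa = a1 == a2
    fb = b1 == b2
    cross = ((a1 == b1).astype(int) + (a1 == b2) + (a2 == b1) + (a2 == b2))
    a_in_b = (a1 == b1) | (a1 == b2)  # under fa, whether a's allele is in b
    b_in_a = (b1 == a1) | (b1 == a2)
    state = np.empty(a1.shape[0], dtype=np.int8)
    state[fa & fb & (a1 == b1)] = 0
    state[fa & fb & (a1 != b1)] = 1
    state[fa & ~fb & a_in_b] = 2
    state[fa & ~fb & ~a_in_b] = 3
    state[~fa & fb & b_in_a] = 4
    state[~fa & fb & ~b_in_a] = 5
    state[~fa & ~fb & (cross == 2)] = 6
    state[~fa & ~fb & (cross == 1)] = 7
    state[~fa & ~fb & (cross == 0)] = 8
    return np.bincount(state, minlength=N_STATES) / state.shape[0]


# --- built-in validation scenarios ---------------------------------------

def scenario_pedigree(scenario: int) -> tuple[Pedigree, tuple[str, str]]:
    """One of the three built-in validation pedigrees and its focal pair.

    All three start from a grandparental founder couple (GF, GM) with two
    children P1 and P2 (full siblings), so the focal individuals are
    cousins through P1 and P2.

    Scenario 1: outbred first cousins (A, B): A = P1 x F1, B = P2 x F2
    with F1, F2 unrelated founders.  Expected (J8, J9) = (1/4, 3/4).

    Scenario 2: B's parents are in a parent-child relation (B = P2 x GM),
    making B inbred with F = 1/4; A as in Scenario 1.  Expected
    (J5, J6, J8, J9) = (1/16, 3/16, 3/8, 3/8).

    Scenario 3: additionally A2's parents are related with the kinship of
    a grandparent-grandchild pair (1/8): A2 = P1 x H where H = GM x F3 is
    a maternal half-sibling of P1, so A2 is inbred with F = 1/8.  The
    focal pair is (B, A2), the Scenario-2 inbred individual first.
    """
    base: list[tuple[str, str | None, str | None]] = [
        ("GF", None, None), ("GM", None, None),
        ("F1", None, None), ("F2", None, None),
        ("P1", "GF", "GM"), ("P2", "GF", "GM"),
    ]
    if scenario == 1:
        trios = base + [("A", "P1", "F1"), ("B", "P2", "F2")]
        return Pedigree(trios), ("A", "B")
    if scenario == 2:
        trios = base + [("A", "P1", "F1"), ("B", "P2", "GM")]
        return Pedigree(trios), ("A", "B")
    if scenario == 3:
        trios = base + [
            ("F3", None, None),
            ("B", "P2", "GM"),
            ("H", "GM", "F3"), ("A2", "P1", "H"),
        ]
        return Pedigree(trios), ("B", "A2")
    raise ValueError(f"unknown scenario {scenario!r}; choose 1, 2 or 3")


def simulate_scenario(
    scenario: int,
    params: SimParams,
) -> tuple[dict[str, np.ndarray], np.ndarray, tuple[str, str], GenomeSet]:
    """Simulate one replicate of a built-in scenario.

    Returns ``(gls, freqs, pair, genomes)`` where ``gls`` holds the GL
    tables of the focal pair only and ``freqs`` the true site frequencies
    used by the estimator.
    """
    ped, pair = scenario_pedigree(scenario)
    rng = np.random.default_rng(params.seed)
    # independent child seeds for the three stochastic stages
    s_freq, s_drop, s_reads = rng.integers(0, 2**31 - 1, size=3)
    freqs = sample_frequencies(params.n_sites, params.maf, s_freq)
    genomes = gene_drop(ped, freqs, s_drop)
    read_params = SimParams(
        n_sites=params.n_sites, depth=params.depth, error=params.error,
        maf=params.maf, seed=int(s_reads),
    )
    gls = simulate_gls(genomes, read_params, individuals=list(pair))
    return gls, freqs, pair, genomes
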