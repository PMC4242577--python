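"""Haplotype/nucleotide diversity and coalescent neutrality tests.

Statistics follow the standard per-site conventions: sites containing
any gap ('-') or ambiguous base ('N') are excluded listwise before
anything is computed, so S, pi and theta_S all refer to the same set of
complete sites.

* h  = n (1 - sum p_i^2) / (n - 1) over haplotype frequencies
* theta_S = S / (a1 * L), a1 = sum_{i=1}^{n-1} 1/i (Watterson)
* pi = mean pairwise difference per site
* Tajima's D (Tajima 1989) and Fu & Li's D*, F* (Fu & Li 1993, the
  "star" statistics that need no outgroup; singletons are sites whose
  minor allele occurs in exactly one sequence).

Significance is assessed against neutral coalescent simulations of a
large, panmictic population conditioned on the observed number of
segregating sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from cphylo.errors import ArgumentError, DegenerateDataError

VALID_CHARS = set("ACGTN-")


@dataclass
class Alignment:
    """Equal-length nucleotide sequences."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ArgumentError("ids and seqs differ in length")
        if len(self.seqs) < 2:
            raise ArgumentError("alignment needs >= 2 sequences")
        L = len(self.seqs[0])
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != L:
                raise ArgumentError(f"sequence {sid!r} has length {len(s)}, expected {L}")
            bad = set(s.upper()) - VALID_CHARS
            if bad:
                raise ArgumentError(f"sequence {sid!r} contains invalid characters {bad}")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @classmethod
    def read_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        return cls(ids=[r.id for r in records], seqs=[str(r.seq) for r in records])

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, s in zip(self.ids, self.seqs):
                fh.write(f">{sid}\n{s}\n")


@dataclass
class DiversityStats:
    n: int
    L: int
    S: int
    N_h: int
    h: float
    theta_S: float
    pi: float
    tajima_D: float | None
    fu_li_Dstar: float | None
    fu_li_Fstar: float | None


# -- internal: constants and count-based statistics -------------------


def _harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n))


def tajima_D_from_counts(n: int, counts: np.ndarray) -> float | None:
    """Tajima's D from per-site minor/derived allele counts (1..n-1)."""
    S = len(counts)
    if S == 0 or n < 4:
        return None
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi_total = float(np.sum(2.0 * counts * (n - counts)) / (n * (n - 1)))
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return None
    return (pi_total - S / a1) / math.sqrt(var)


def _fu_li_constants(n: int) -> tuple[float, float, float, float]:
    """(uD*, vD*, uF*, vF*) for the no-outgroup star statistics."""
    a = _harmonic(n)
    b = _harmonic(n, 2)
    an1 = a + 1.0 / n  # a_{n+1}
    if n > 2:
        c = 2.0 * (n * a - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    else:
        c = 1.0
    if n > 2:
        d = c + (n - 2.0) / (n - 1) ** 2 + (2.0 / (n - 1)) * (1.5 - (2.0 * an1 - 3.0) / (n - 2) - 1.0 / n)
    else:
        d = c
    vD = ((n / (n - 1.0)) ** 2 * b + a**2 * d - 2.0 * (n * a * (a + 1.0)) / (n - 1.0) ** 2) / (a**2 + b)
    uD = (n / (n - 1.0)) * (a - n / (n - 1.0)) - vD
    vF = (d + 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0)) - (2.0 / (n - 1.0)) * (4.0 * b - 6.0 + 8.0 / n)) / (
        a**2 + b
    )
    uF = (
        n / (n - 1.0)
        + (n + 1.0) / (3.0 * (n - 1.0))
        - 4.0 / (n * (n - 1.0))
        + 2.0 * (n + 1.0) / (n - 1.0) ** 2 * (an1 - 2.0 * n / (n + 1.0))
    ) / a - vF
    return uD, vD, uF, vF


def fu_li_from_counts(n: int, counts: np.ndarray) -> tuple[float | None, float | None]:
    """Fu & Li's (D*, F*) from per-site allele counts.

    ``counts`` are derived (or minor) allele counts; a singleton is a
    site whose minor allele count equals 1, which needs no outgroup.
    """
    eta = len(counts)
    if eta == 0 or n < 4:
        return None, None
    counts = np.asarray(counts)
    minor = np.minimum(counts, n - counts)
    eta_s = int(np.sum(minor == 1))
    a = _harmonic(n)
    uD, vD, uF, vF = _fu_li_constants(n)
    pi_total = float(np.sum(2.0 * counts * (n - counts)) / (n * (n - 1)))
    varD = uD * eta + vD * eta**2
    varF = uF * eta + vF * eta**2
    Dstar = ((n / (n - 1.0)) * eta - a * eta_s) / math.sqrt(varD) if varD > 0 else None
    Fstar = (pi_total - ((n - 1.0) / n) * eta_s) / math.sqrt(varF) if varF > 0 else None
    return Dstar, Fstar


# -- public API -------------------------------------------------------


def site_counts(alignment: Alignment) -> tuple[int, np.ndarray]:
    """(L_complete, minor-allele counts of each segregating site).

    Only sites free of gaps/N in every sequence are considered.  Sites
    with more than two states still contribute: the count reported is
    n minus the majority-state count, matching the pairwise-difference
    accounting only for biallelic sites (multiallelic complete sites
    are rare in these data and counted by minor-state total).
    """
    arr = np.array([list(s) for s in alignment.seqs])
    complete = ~np.isin(arr, ["-", "N"]).any(axis=0)
    arr = arr[:, complete]
    L = arr.shape[1]
    counts = []
    for j in range(L):
        col = arr[:, j]
        _, c = np.unique(col, return_counts=True)
        if len(c) > 1:
            counts.append(alignment.n - int(c.max()))
    return L, np.array(counts, dtype=int)


def _pairwise_pi_total(alignment: Alignment) -> tuple[int, float]:
    """(complete length, mean pairwise differences over complete sites)."""
    arr = np.array([list(s) for s in alignment.seqs])
    complete = ~np.isin(arr, ["-", "N"]).any(axis=0)
    arr = arr[:, complete]
    n = alignment.n
    diffs = 0
    for i in range(n):
        for j in range(i + 1, n):
            diffs += int((arr[i] != arr[j]).sum())
    return arr.shape[1], diffs / (n * (n - 1) / 2.0)


def diversity(alignment: Alignment, site_filter: str = "complete_only") -> DiversityStats:
    """All Table-style diversity and neutrality statistics for one locus."""
    if site_filter != "complete_only":
        raise ArgumentError(f"unknown site filter {site_filter!r}")
    n = alignment.n
    L, counts = site_counts(alignment)
    if L == 0:
        raise DegenerateDataError("no complete sites left after filtering")
    S = len(counts)

    # haplotypes over complete sites
    arr = np.array([list(s) for s in alignment.seqs])
    complete = ~np.isin(arr, ["-", "N"]).any(axis=0)
    haplos = ["".join(row) for row in arr[:, complete]]
    _, freq = np.unique(haplos, return_counts=True)
    p = freq / n
    N_h = len(freq)
    h = n * (1.0 - float(np.sum(p**2))) / (n - 1.0)

    a1 = _harmonic(n)
    theta_S = S / (a1 * L)
    _, pi_total = _pairwise_pi_total(alignment)
    pi = pi_total / L

    if S > 0:
        D = tajima_D_from_counts(n, counts)
        Dstar, Fstar = fu_li_from_counts(n, counts)
    else:
        D = Dstar = Fstar = None
    return DiversityStats(
        n=n, L=L, S=S, N_h=N_h, h=h, theta_S=theta_S, pi=pi,
        tajima_D=D, fu_li_Dstar=Dstar, fu_li_Fstar=Fstar,
    )


def _null_statistics(n: int, S: int, reps: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Null distributions of (D, D*, F*) from fixed-S coalescent draws."""
    from cphylo.simulate import simulate_segregating_counts

    out = {"tajima_D": [], "fu_li_Dstar": [], "fu_li_Fstar": []}
    for _ in range(reps):
        counts = simulate_segregating_counts(n, S, rng)
        D = tajima_D_from_counts(n, counts)
        Dstar, Fstar = fu_li_from_counts(n, counts)
        out["tajima_D"].append(D)
        out["fu_li_Dstar"].append(Dstar)
        out["fu_li_Fstar"].append(Fstar)
    return {k: np.array([v for v in vals if v is not None]) for k, vals in out.items()}


def neutrality_pvalues(
    stats: DiversityStats, reps: int = 1000, seed: int = 0
) -> dict[str, float | None]:
    """Two-tailed coalescent p-values for D, D* and F*.

    ``reps`` neutral samples of the same n are simulated conditioned on
    the observed S; p = 2 * min(lower tail, upper tail) with add-one
    correction, capped at 1.  Undefined statistics get p = None.
    """
    if stats.S < 1:
        raise ArgumentError("neutrality test requires S >= 1")
    rng = np.random.default_rng(seed)
    null = _null_statistics(stats.n, stats.S, reps, rng)
    observed = {
        "tajima_D": stats.tajima_D,
        "fu_li_Dstar": stats.fu_li_Dstar,
        "fu_li_Fstar": stats.fu_li_Fstar,
    }
    pvals: dict[str, float | None] = {}
    for name, obs in observed.items():
        if obs is None or len(null[name]) == 0:
            pvals[name] = None
            continue
        dist = null[name]
        m = len(dist)
        lower = (1 + int(np.sum(dist <= obs))) / (1 + m)
        upper = (1 + int(np.sum(dist >= obs))) / (1 + m)
        pvals[name] = min(1.0, 2.0 * min(lower, upper))
    return pvals
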