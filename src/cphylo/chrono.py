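"""Chronograms and substitution-rate / calendar-age conversion.

A chronogram is a rooted binary ultrametric tree whose branch lengths
are either substitutions/site (as estimated from sequence data) or
years.  Conversion between the two scales uses a per-generation
mutation rate ``mu`` with stated error ``sigma`` and a generation time
in years:

    age_in_years = (height_in_subst_per_site / mu) * generation_time

Rate error propagates multiplicatively: an age estimated with rate
``mu`` would have been ``age * mu / (mu + sigma)`` under the faster
end of the rate range and ``age * mu / (mu - sigma)`` under the slower
end, which brackets the nominal age.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from cphylo.errors import ArgumentError, FormatError

SUBST = "substitutions/site"
YEARS = "years"


@dataclass
class RateModel:
    """Per-generation mutation rate with symmetric error.

    mu : substitutions/site/generation (> 0)
    sigma : stated error of mu (0 <= sigma < mu)
    generation_time : years per generation (> 0)
    """

    mu: float
    sigma: float = 0.0
    generation_time: float = 2.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ArgumentError(f"mu must be > 0, got {self.mu}")
        if not (0 <= self.sigma < self.mu):
            raise ArgumentError(
                f"sigma must satisfy 0 <= sigma < mu, got sigma={self.sigma}, mu={self.mu}"
            )
        if self.generation_time <= 0:
            raise ArgumentError("generation_time must be > 0")


class Chronogram:
    """Rooted tree with branch lengths in a declared unit.

    Thin wrapper around a :class:`dendropy.Tree` adding unit tracking,
    node ages, and an ultrametricity check.
    """

    def __init__(self, tree: dendropy.Tree, unit: str = YEARS):
        if unit not in (SUBST, YEARS):
            raise ArgumentError(f"unknown branch-length unit {unit!r}")
        self.tree = tree
        self.unit = unit

    # -- I/O ----------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, unit: str = YEARS) -> "Chronogram":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise FormatError(f"newick parse failure: {exc}") from exc
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node and edge.length is None:
                raise FormatError(
                    f"newick branch without length above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
                )
        return cls(tree, unit=unit)

    @classmethod
    def read(cls, path, unit: str = YEARS) -> "Chronogram":
        with open(path) as fh:
            return cls.from_newick(fh.read(), unit=unit)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- structure ----------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def node_ages(self) -> dict[dendropy.Node, float]:
        """Age of every node = max root-to-tip depth minus node depth.

        On an exactly ultrametric tree tip ages are 0 and the root age
        equals the tree height.
        """
        depth: dict[dendropy.Node, float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depth[node] = 0.0
            else:
                depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        height = max(depth[leaf] for leaf in self.tree.leaf_node_iter())
        return {node: height - d for node, d in depth.items()}

    @property
    def root_height(self) -> float:
        return self.node_ages()[self.tree.seed_node]

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        ages = self.node_ages()
        height = self.root_height
        if height == 0:
            return True
        return all(
            abs(ages[leaf]) <= rel_tol * height for leaf in self.tree.leaf_node_iter()
        )

    def to_years(self, rate: RateModel) -> "Chronogram":
        """Rescale a substitutions/site tree to calendar years."""
        if self.unit != SUBST:
            raise ArgumentError("tree is not on the substitutions/site scale")
        clone = self.tree.clone(depth=1)
        factor = rate.generation_time / rate.mu
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return Chronogram(clone, unit=YEARS)


def parse_newick(text: str, unit: str = YEARS) -> Chronogram:
    """Module-level convenience alias for :meth:`Chronogram.from_newick`."""
    return Chronogram.from_newick(text, unit=unit)


def age_from_height(height: float, rate: RateModel) -> float:
    """Calendar age (years) of a node at ``height`` substitutions/site."""
    if height < 0:
        raise ArgumentError(f"height must be >= 0, got {height}")
    return (height / rate.mu) * rate.generation_time


def height_from_age(age_years: float, rate: RateModel) -> float:
    """Inverse of :func:`age_from_height`."""
    if age_years < 0:
        raise ArgumentError(f"age must be >= 0, got {age_years}")
    return age_years * rate.mu / rate.generation_time


def rate_uncertainty_bounds(nominal_age: float, rate: RateModel) -> tuple[float, float]:
    """(low, high) age bracket induced by the rate error.

    The same substitution-scale height converted with mu + sigma gives
    the younger bound and with mu - sigma the older bound:

        low  = nominal_age * mu / (mu + sigma)
        high = nominal_age * mu / (mu - sigma)
    """
    if rate.sigma >= rate.mu:
        raise ArgumentError("sigma >= mu would make the upper bound infinite")
    low = nominal_age * rate.mu / (rate.mu + rate.sigma)
    high = nominal_age * rate.mu / (rate.mu - rate.sigma)
    return low, high


def round_ky(age_years: float) -> int:
    """Report an age in integer kiloyears, rounding half-up."""
    import math

    return int(math.floor(age_years / 1000.0 + 0.5))
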