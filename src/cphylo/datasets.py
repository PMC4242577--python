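"""Packaged fixture data for the Cordilleran bellflower radiation.

Published per-taxon morphology parameters (grand means with SDs for
the continuous floral/vegetative characters; categorical levels for
floral, vegetative and seed characters), the six-refugium area fixture
with its adjacency list, and two clearly-labeled synthetic stand-ins
for unpublished inputs:

* ``range_matrix_synthetic.csv`` -- a plausible taxon x refugium 0/1
  matrix (the matrix actually used in the original analysis was never
  deposited); an assumption, not data.
* ``chronogram_synthetic.nwk`` -- an ultrametric tree (branch lengths
  in kiloyears, fast-rate scaling) that encodes the published crown
  ages of 1030, 560, 510, 386 and 240 KY; the two internal nodes
  joining the three subclades are unpublished and are an assumption of
  this fixture (770 KY here).

The lower-leaf / seed block of the categorical table is misaligned in
the source document; the reconstruction shipped here (including the
seed row for *scouleri*, which the source omits) is documented in the
file name and should be treated as synthetic.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from cphylo.chrono import Chronogram
from cphylo.dec import AreaSet, DEFAULT_AREAS, read_range_matrix
from cphylo.simulate import MorphSpec

#: Per-taxon morphology sample sizes (published Table of characters).
MORPH_SAMPLE_SIZES = {
    "aurita": 10,
    "lasiocarpa": 10,
    "idahoensis": 20,
    "parryi": 10,
    "piperi": 40,
    "scabrella": 30,
    "scouleri": 10,
}

#: Character groups used in the classification-tree comparisons.
FLORAL_CHARACTERS = ("flowers_per_stem", "flower_shape", "hypanthium_hair", "pollen_color")
VEGETATIVE_CHARACTERS = (
    "upper_leaf_shape",
    "upper_leaf_margin",
    "lower_leaf_shape",
    "lower_leaf_margin",
)
SEED_CHARACTERS = ("seed_wings", "seed_shape_long", "seed_cross_section", "seed_surface")

#: Continuous characters entering the discriminant analysis whose
#: distributions are log10-transformed (skewed length measurements).
LDA_LOG_COLUMNS = (
    "corolla_length",
    "hypanthium_length_width",
    "corolla_height",
    "fused_corolla_length",
    "sepal_length",
    "stem_length",
)


def _data(name: str):
    return files("cphylo.data").joinpath(name)


def morph_categorical_table() -> pd.DataFrame:
    """Per-taxon categorical levels (taxon-indexed, one row per taxon)."""
    return pd.read_csv(_data("morph_categorical_reconstructed.csv"), index_col="taxon", dtype=str)


def morph_continuous_table() -> pd.DataFrame:
    """Per-taxon (mean, sd) of the continuous characters, long format."""
    return pd.read_csv(_data("morph_continuous.csv"), index_col="character")


def morph_spec() -> MorphSpec:
    """MorphSpec over the published per-taxon parameters.

    Characters without a published SD (literature-derived seed metrics)
    are excluded from the continuous block.
    """
    cat = morph_categorical_table()
    cont = morph_continuous_table()
    continuous: dict[str, dict[str, tuple[float, float]]] = {}
    categorical: dict[str, dict[str, str]] = {}
    for taxon in MORPH_SAMPLE_SIZES:
        per_char = {}
        for char, row in cont.iterrows():
            mean, sd = row[f"{taxon}_mean"], row[f"{taxon}_sd"]
            if pd.notna(sd):
                per_char[char] = (float(mean), float(sd))
        continuous[taxon] = per_char
        categorical[taxon] = cat.loc[taxon].to_dict()
    return MorphSpec(
        continuous=continuous,
        categorical=categorical,
        sample_sizes=dict(MORPH_SAMPLE_SIZES),
    )


def area_adjacency() -> list[tuple[str, str]]:
    """Editable refugium adjacency used to build dispersal matrices."""
    df = pd.read_csv(_data("areas_adjacency.csv"))
    return [(str(a), str(b)) for a, b in zip(df["area_a"], df["area_b"])]


def synthetic_range_matrix() -> dict[str, frozenset[str]]:
    """Synthetic taxon x refugium ranges (assumption; see module docs)."""
    return read_range_matrix(_data("range_matrix_synthetic.csv"), AreaSet(DEFAULT_AREAS))


def synthetic_chronogram() -> Chronogram:
    """Synthetic ultrametric fixture tree, branch lengths in kiloyears."""
    return Chronogram.from_newick(_data("chronogram_synthetic.nwk").read_text(), unit="years")
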