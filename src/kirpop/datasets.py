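"""Packaged reference tables for the HGDP-CEPH KIR survey.

Two small CSVs ship with the package:

``hgdp_populations.csv``
    The 52 HGDP-CEPH population samples: name, world region, sample size and
    geographic coordinates.  Coordinates printed as ranges in the source table
    are resolved to midpoints (south and west negative).  A few entries are
    garbled in the source ("30-31"/"66-67 E" for the Biaka Pygmies, "4 N 17 E"
    for the Bedouin, "31 N 35 E" for the Barusho, "6972 E" for the Pathan);
    they are stored as printed, resolved literally, and marked in the
    ``coordinates_flagged`` column rather than silently corrected.

``hgdp_kir_frequencies.csv``
    Published carrier and gene frequencies for the 16 KIR loci in each of the
    52 populations (two rows per population, ``kind`` in {carrier, gene}),
    printed to three decimals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .kir_data import KIR_LOCI


def _data_path(name: str):
    return resources.files("kirpop.data").joinpath(name)


def load_hgdp_metadata() -> pd.DataFrame:
    """Population metadata, indexed by population name.

    Columns: region, n, latitude, longitude, latitude_printed,
    longitude_printed, coordinates_flagged.
    """
    with resources.as_file(_data_path("hgdp_populations.csv")) as p:
        df = pd.read_csv(p, index_col="population")
    df["coordinates_flagged"] = df["coordinates_flagged"].astype(bool)
    return df


def load_hgdp_frequencies(kind: str = "carrier") -> pd.DataFrame:
    """Published frequency table (population x 16 loci) of the given kind.

    ``kind`` is ``"carrier"`` (fraction of individuals in whom the locus is
    detected) or ``"gene"`` (estimated chromosome-level frequency).
    """
    if kind not in ("carrier", "gene"):
        raise ValueError("kind must be 'carrier' or 'gene'")
    with resources.as_file(_data_path("hgdp_kir_frequencies.csv")) as p:
        df = pd.read_csv(p)
    df = df[df["kind"] == kind].set_index("population")[list(KIR_LOCI)]
    meta = load_hgdp_metadata()
    return df.loc[meta.index]  # metadata row order
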