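"""Packaged reference network: the frog hindlimb musculoskeletal system.

The fixture is the published 54-node network of the pelvic girdle and
hindlimb of the frog *Leptodactylus latinasus*: 20 bones, 27 muscles and 7
fibrous knots, with 102 edges encoding joints and ligamentous/tendinous
contacts, transcribed from the printed adjacency table together with the
published five-module partition (Hip, Thigh, Shank, Calf, Foot).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .graph import AnatomicalNetwork, Partition, load_network

__all__ = ["frog_hindlimb_fixture", "frog_published_partition"]

_DATA_FILE = "frog_hindlimb.csv"


def _fixture_table() -> pd.DataFrame:
    with resources.files("anna.data").joinpath(_DATA_FILE).open() as fh:
        return pd.read_csv(fh, dtype=str, keep_default_na=False)


def frog_hindlimb_fixture() -> AnatomicalNetwork:
    """The packaged 54-node frog hindlimb network.

    Node ids 1-54 follow the published table; the published module labels are
    attached as ``published_module`` on every node.  The adjacency-list input
    form is re-validated for symmetry on every load.
    """
    return load_network(_fixture_table())


def frog_published_partition(
    net: AnatomicalNetwork | None = None,
) -> Partition:
    """The published five-module partition (Hip, Thigh, Shank, Calf, Foot)."""
    if net is None:
        net = frog_hindlimb_fixture()
    return net.published_partition()
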