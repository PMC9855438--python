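"""Access to the small data files shipped with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .interactions import read_pairs
from .scoring import GeneSet, read_gmt


def _data_path(name: str):
    return resources.files("tmecompare").joinpath("data", name)


def literature_signatures() -> list[GeneSet]:
    """Editable literature-derived score gene lists (Treg, cytotoxicity, ...)."""
    with resources.as_file(_data_path("literature_signatures.gmt")) as p:
        return read_gmt(p)


def curated_lr_pairs() -> pd.DataFrame:
    """Small curated ligand-receptor table (NOTCH and TGFB families)."""
    with resources.as_file(_data_path("lr_pairs.tsv")) as p:
        return read_pairs(p)
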