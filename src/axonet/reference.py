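"""Bundled reference values from paired recordings, for comparison plots."""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd

__all__ = ["experimental_coupling_bands"]


def experimental_coupling_bands() -> pd.DataFrame:
    """Distance-banded experimental coupling coefficients (percent).

    Returns one row per soma-separation band with the low/high edge of
    the reported coefficient range, for overlaying on model
    coupling-versus-distance summaries.
    """
    text = (
        resources.files("axonet.data")
        .joinpath("experimental_coupling.csv")
        .read_text()
    )
    return pd.read_csv(StringIO(text), comment="#")
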