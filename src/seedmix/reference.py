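"""Reference bookkeeping for the open Carpeso seed-mix image dataset.

Summary statistics of the deposited acquisition campaign (Zenodo,
DOI 10.5281/zenodo.8169473): images collected per year and per mix type over
the 2019–2021 campaign, and the mix-level train/validation partition used
with it.  These tables let manifest-handling code be checked against the real
campaign's totals without downloading the dataset itself.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "acquisition_campaign",
    "campaign_total_images",
    "split_summary",
    "split_total_mixes",
]


def acquisition_campaign() -> pd.DataFrame:
    """Images per year and mix type in the deposited campaign."""
    return pd.DataFrame(
        [
            {"year": 2019, "monocrop": 0, "composition": 0, "real": 465},
            {"year": 2020, "monocrop": 1228, "composition": 0, "real": 659},
            {"year": 2021, "monocrop": 0, "composition": 2243, "real": 154},
        ]
    ).set_index("year")


def campaign_total_images() -> int:
    """Total image count, recomputed by summing the per-year/per-type cells."""
    df = acquisition_campaign()
    return int(df.to_numpy().sum())


def split_summary() -> pd.DataFrame:
    """Mixes and images on each side of the deposited train/validation split."""
    return pd.DataFrame(
        [
            {"dataset": "train", "mixes": 163, "images": 3805},
            {"dataset": "validation", "mixes": 42, "images": 944},
        ]
    ).set_index("dataset")


def split_total_mixes() -> tuple[int, int]:
    """(total mixes, total images) recomputed by summing the split rows."""
    df = split_summary()
    return int(df["mixes"].sum()), int(df["images"].sum())
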