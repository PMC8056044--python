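"""Shared test helpers for building small score tables."""

import numpy as np
import pandas as pd

from netprio.datatypes import FunctionalScoreTable


def make_fs_table(fs_values: dict[str, float]) -> FunctionalScoreTable:
    """Build a score table from raw FS values (mean_uppr = 10**-FS)."""
    fs = pd.Series(fs_values, dtype=float)
    return FunctionalScoreTable(
        pd.DataFrame({"mean_uppr": 10.0 ** (-fs), "FS": fs})
    )


def make_ps(values: dict[str, float]) -> pd.Series:
    return pd.Series(values, dtype=float, name="PS")


def random_scores(rng: np.random.Generator, n: int, with_ties: bool):
    """Random (FS, PS) table; with_ties quantizes to force duplicates."""
    fs = rng.exponential(1.0, n)
    ps = rng.exponential(1.0, n)
    if with_ties:
        fs = np.round(fs, 1)
        ps = np.round(ps, 1)
    genes = [f"G{i:05d}" for i in range(n)]
    table = FunctionalScoreTable(
        pd.DataFrame({"mean_uppr": np.clip(10.0 ** (-fs), 0, 1), "FS": fs},
                     index=genes)
    )
    return table, pd.Series(ps, index=genes, name="PS")
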