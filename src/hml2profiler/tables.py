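"""Loaders for the packaged published frequency tables.

Three tables from a published Sanger-sequencing survey of HML-2 transcription
in ALS and control CNS tissue ship with the package as TSV fixtures: relative
cloning frequencies of the gag amplicon by tissue group, of the env 5' region
amplicon by sample, and of the rec/np9 amplicon by sample and product-length
class. Percentages are converted back to integer clone counts using the
per-column totals (count = round-half-up(pct * total / 100)); the counts
reproduce the printed percentages exactly, which the test suite pins.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .quantify import FrequencyTable, round_half_up

_META_COLUMNS = ("provirus_type", "env_aa", "rec_np9", "hg19_anchor")


@dataclass
class PublishedTable:
    """One published table: counts/frequencies plus per-locus metadata."""

    name: str
    frequency: FrequencyTable
    locus_meta: pd.DataFrame
    totals: dict[str, int]
    condition: dict[str, str]  # sample/group -> ALS | control
    n_samples: dict[str, int]  # per group, where published


def _data_path(filename: str):
    return resources.files("hml2profiler").joinpath("data", filename)


def _parse_keyed_line(line: str) -> dict[str, str]:
    out = {}
    for token in line.split("\t")[1:]:
        token = token.strip()
        if token:
            key, value = token.split("=", 1)
            out[key] = value
    return out


def _load(filename: str, name: str) -> PublishedTable:
    path = _data_path(filename)
    totals: dict[str, int] = {}
    condition: dict[str, str] = {}
    n_samples: dict[str, int] = {}
    with path.open() as handle:
        for line in handle:
            if line.startswith("#total_sequences"):
                totals = {k: int(v) for k, v in _parse_keyed_line(line).items()}
            elif line.startswith("#condition"):
                condition = _parse_keyed_line(line)
            elif line.startswith("#n_samples"):
                n_samples = {k: int(v) for k, v in _parse_keyed_line(line).items()}
    with path.open() as handle:
        frame = pd.read_csv(handle, sep="\t", comment="#", index_col=0)
    value_cols = [c for c in frame.columns if c in totals]
    meta_cols = [c for c in frame.columns if c in _META_COLUMNS]
    pct = frame[value_cols].astype(float).fillna(0.0)
    totals_series = pd.Series({c: totals[c] for c in value_cols})
    counts = pct.apply(
        lambda col: col.map(lambda p: int(round_half_up(p * totals[col.name] / 100.0, 0))),
        axis=0,
    )
    if not condition:
        condition = {c: ("ALS" if c.startswith("ALS") else "control") for c in value_cols}
    return PublishedTable(
        name=name,
        frequency=FrequencyTable(counts, totals_series),
        locus_meta=frame[meta_cols],
        totals={c: totals[c] for c in value_cols},
        condition=condition,
        n_samples=n_samples,
    )


def load_gag_table() -> PublishedTable:
    """gag-amplicon cloning frequencies by tissue group (6 groups, 820 clones)."""
    return _load("gag_amplicon_frequencies.tsv", "gag")


def load_env_table() -> PublishedTable:
    """env 5' region amplicon cloning frequencies by sample (7 samples, 144 clones)."""
    return _load("env_amplicon_frequencies.tsv", "env600nt")


def load_rec_np9_table() -> PublishedTable:
    """rec/np9 amplicon cloning frequencies by sample and product class (211 clones)."""
    return _load("rec_np9_amplicon_frequencies.tsv", "rec_np9")
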