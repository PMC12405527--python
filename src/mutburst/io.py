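"""Table and manifest I/O.

Fluctuation tables are tab-separated UTF-8 with dataset-level metadata in
``#`` pragma lines (``# key=value``) above the header::

    # label=wt_D
    # cells_per_culture=134217728
    # plating_fraction=1.0
    culture_id	mutant_count
    c0001	0

Numeric columns are written at repr-roundtrip precision; manifests are JSON.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fluctuation import FluctuationDataset, InputError, RateEstimate

__all__ = [
    "read_fluctuation_tsv",
    "write_fluctuation_tsv",
    "write_estimates_tsv",
    "estimates_to_dataframe",
    "write_manifest",
    "read_manifest",
]


def write_fluctuation_tsv(dataset: FluctuationDataset, path) -> None:
    path = Path(path)
    lines = [
        f"# label={dataset.label}",
        f"# cells_per_culture={dataset.cells_per_culture!r}",
        f"# plating_fraction={dataset.plating_fraction!r}",
        "culture_id\tmutant_count",
    ]
    lines += [
        f"c{i + 1:04d}\t{int(c)}" for i, c in enumerate(dataset.counts)
    ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_fluctuation_tsv(path) -> FluctuationDataset:
    path = Path(path)
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            pragma = line.lstrip("#").strip()
            if "=" in pragma:
                key, _, value = pragma.partition("=")
                meta[key.strip()] = value.strip()
        elif line.strip():
            body.append(line)
    if "cells_per_culture" not in meta:
        raise InputError(
            f"{path}: missing '# cells_per_culture=' pragma"
        )
    table = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t")
    if "mutant_count" not in table.columns:
        raise InputError(f"{path}: missing 'mutant_count' column")
    return FluctuationDataset(
        counts=table["mutant_count"].to_numpy(dtype=np.int64),
        cells_per_culture=float(meta["cells_per_culture"]),
        plating_fraction=float(meta.get("plating_fraction", 1.0)),
        label=meta.get("label", path.stem),
    )


def estimates_to_dataframe(estimates: list[RateEstimate]) -> pd.DataFrame:
    """One row per dataset: m_hat, rate (per cell per division), 95% CI."""
    return pd.DataFrame(
        {
            "label": [e.label for e in estimates],
            "m_hat": [e.m_hat for e in estimates],
            "rate": [e.rate for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
            "n_cultures": [e.n_cultures for e in estimates],
            "degenerate": [e.degenerate for e in estimates],
        }
    )


def write_estimates_tsv(estimates: list[RateEstimate], path) -> None:
    estimates_to_dataframe(estimates).to_csv(path, sep="\t", index=False)


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
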