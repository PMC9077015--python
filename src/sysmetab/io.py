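"""Plain-text readers and writers for the pipeline's interchange formats.

Spectra are two-column delimited text (ppm, intensity), one file per
sample, with a tab-separated manifest (sample_id, group, filename).
Tables are TSV.  Pathway libraries use the GMT-like membership format plus
a topology edge list (see :mod:`sysmetab.library`).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .nmr import Spectrum

__all__ = [
    "write_spectra",
    "read_spectra",
    "write_table",
    "read_table",
]


def write_spectra(spectra: Iterable[Spectrum], directory) -> Path:
    """Write one ``<sample_id>.tsv`` per spectrum plus ``manifest.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in spectra:
        fname = f"{s.sample_id}.tsv"
        np.savetxt(
            directory / fname,
            np.column_stack([s.ppm, s.intensity]),
            fmt="%.6f\t%.6e",
            header="ppm\tintensity",
            comments="",
        )
        rows.append({"sample_id": s.sample_id, "group": s.group, "file": fname})
    manifest = directory / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_spectra(manifest_path) -> list[Spectrum]:
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep="\t")
    spectra = []
    for _, row in manifest.iterrows():
        data = np.loadtxt(directory / row["file"], skiprows=1)
        spectra.append(
            Spectrum(data[:, 0], data[:, 1], sample_id=row["sample_id"], group=row["group"])
        )
    return spectra


def write_table(frame: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
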