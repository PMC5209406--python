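"""Packaged training and test data for the chloride-gemini cmc study.

The training fixture is the printed descriptor matrix of the 23 chloride
gemini surfactants: the ten connectivity indices and the experimental
log10 cmc (molar scale, pure water, 25 degrees C) per compound.  The
numbers are a frozen transcription, guarded by a digest so silent edits
surface as errors rather than as drifting regression results.

The two test compounds come with experimental logcmc only; their
descriptor values are computed on load from packaged structure
transcriptions and are flagged ``derived`` because no printed reference
values exist for them.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .chi_indices import DESCRIPTOR_COLUMNS, descriptor_row
from .molgraph import MolecularGraph, parse_smiles_file

__all__ = ["DescriptorRow", "QsprDataset", "DatasetError", "load_training", "load_test", "load_structures"]

INDEX_COLUMNS: tuple[str, ...] = tuple(DESCRIPTOR_COLUMNS)

_TRAINING_SHA256 = "38b16d95d707f6adb99b81bb33cd5e55ebac677946d740453290658a83d5e904"


class DatasetError(RuntimeError):
    """Raised when a packaged fixture fails its integrity check."""


@dataclass(frozen=True)
class DescriptorRow:
    """One compound: the ten indices plus (optionally) experimental logcmc."""

    name: str
    indices: dict[str, float]
    logcmc: float | None = None
    provenance: str = "printed"  # printed | derived

    def __post_init__(self) -> None:
        missing = [c for c in INDEX_COLUMNS if c not in self.indices]
        if missing:
            raise DatasetError(f"{self.name}: missing index columns {missing}")
        bad = [c for c in INDEX_COLUMNS if not self.indices[c] > 0]
        if bad:
            raise DatasetError(f"{self.name}: nonpositive index values in {bad}")


@dataclass(frozen=True)
class QsprDataset:
    """An ordered set of descriptor rows."""

    rows: tuple[DescriptorRow, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.rows]
        if len(set(names)) != len(names):
            raise DatasetError("duplicate compound names")

    @property
    def n(self) -> int:
        return len(self.rows)

    def row(self, name: str) -> DescriptorRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        """Indices + logcmc as a DataFrame indexed by compound name."""
        data = {c: [r.indices[c] for r in self.rows] for c in INDEX_COLUMNS}
        data["logcmc"] = [r.logcmc for r in self.rows]
        return pd.DataFrame(data, index=pd.Index([r.name for r in self.rows], name="name"))


def _read_packaged(filename: str) -> bytes:
    return resources.files("chiqspr.data").joinpath(filename).read_bytes()


def load_training() -> QsprDataset:
    """The 23-compound training matrix, exactly as printed.

    logcmc spans roughly -4.39 to -2.89.  Raises :class:`DatasetError` if
    the packaged file does not match its embedded digest.
    """
    raw = _read_packaged("table1_training.csv")
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TRAINING_SHA256:
        raise DatasetError(
            f"training fixture corrupted: sha256 {digest} != expected {_TRAINING_SHA256}"
        )
    df = pd.read_csv(io.BytesIO(raw))
    rows = tuple(
        DescriptorRow(
            name=rec["name"],
            indices={c: float(rec[c]) for c in INDEX_COLUMNS},
            logcmc=float(rec["logcmc"]),
            provenance="printed",
        )
        for rec in df.to_dict("records")
    )
    ds = QsprDataset(rows)
    if ds.n != 23:
        raise DatasetError(f"training fixture has {ds.n} rows, expected 23")
    return ds


def load_structures() -> dict[str, MolecularGraph]:
    """Packaged structure transcriptions, keyed by compound name."""
    text = _read_packaged("structures.smi").decode()
    return {g.name: g for g in parse_smiles_file(text.splitlines())}


def load_test() -> QsprDataset:
    """The two test compounds: printed logcmc, descriptors derived on load.

    The descriptor values are computed by the index engine from packaged
    structure transcriptions; they carry provenance ``derived`` because the
    study prints no reference values to validate them against.
    """
    df = pd.read_csv(io.BytesIO(_read_packaged("test_set.csv")))
    structures = load_structures()
    rows = []
    for rec in df.to_dict("records"):
        name = rec["name"]
        if name not in structures:
            raise DatasetError(f"no packaged structure for test compound {name!r}")
        rows.append(
            DescriptorRow(
                name=name,
                indices=descriptor_row(structures[name]),
                logcmc=float(rec["logcmc"]),
                provenance="derived",
            )
        )
    ds = QsprDataset(tuple(rows))
    if ds.n != 2:
        raise DatasetError(f"test fixture has {ds.n} rows, expected 2")
    return ds
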