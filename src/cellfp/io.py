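"""Plain-text I/O for spectra, metadata and feature matrices.

All interfaces present the chemical-shift axis in descending ppm (the NMR
display convention).  Buckets are half-open intervals ``[upper, lower)`` on
that descending axis.  CSV is the single interchange format; vendor formats
are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

EXPERIMENTS = ("cpmg", "excitation_sculpting")
NORMALIZATION_STATES = ("raw", "pqn", "scaled")

META_COLUMNS = ("sample_id", "class_label", "field_mhz", "experiment",
                "mixture_fraction", "extra_json")


@dataclass
class Spectrum:
    """A 1D trace on a strictly descending ppm axis."""

    ppm: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.ppm.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("ppm and intensities must be 1-D")
        if self.ppm.size != self.intensities.size:
            raise ValueError(
                f"length mismatch for {self.sample_id!r}: "
                f"{self.ppm.size} ppm points vs {self.intensities.size} intensities")
        if self.ppm.size >= 2 and not np.all(np.diff(self.ppm) < 0):
            raise ValueError(f"ppm axis of {self.sample_id!r} is not strictly descending")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"non-finite intensities in {self.sample_id!r}")

    def copy(self) -> "Spectrum":
        return Spectrum(self.ppm.copy(), self.intensities.copy(), self.sample_id)


@dataclass
class SampleMeta:
    """Per-sample annotations: class, field strength and experiment type."""

    sample_id: str
    class_label: str | tuple[str, str]
    field_mhz: float
    experiment: str
    mixture_fraction: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.field_mhz <= 0:
            raise ValueError(f"{self.sample_id}: field_mhz must be positive")
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"{self.sample_id}: experiment {self.experiment!r} not in {EXPERIMENTS}")
        is_pair = isinstance(self.class_label, tuple)
        if is_pair:
            a, b = self.class_label
            if a == b:
                raise ValueError(f"{self.sample_id}: mixture classes must differ")
            self.class_label = tuple(sorted((a, b)))  # type: ignore[assignment]
        if is_pair != (self.mixture_fraction is not None):
            raise ValueError(
                f"{self.sample_id}: mixture_fraction must be present iff the "
                "class label is a pair")
        if self.mixture_fraction is not None and not 0 <= self.mixture_fraction <= 1:
            raise ValueError(f"{self.sample_id}: mixture_fraction outside [0, 1]")

    @property
    def label_str(self) -> str:
        if isinstance(self.class_label, tuple):
            return "+".join(self.class_label)
        return self.class_label


class SpectraSet:
    """An ordered collection of spectra on one shared grid plus metadata."""

    def __init__(self, spectra: Sequence[Spectrum], meta: Sequence[SampleMeta]):
        self.spectra = list(spectra)
        meta_by_id = {m.sample_id: m for m in meta}
        if len(meta_by_id) != len(meta):
            seen: set[str] = set()
            for m in meta:
                if m.sample_id in seen:
                    raise ValueError(f"duplicated sample_id {m.sample_id!r} in metadata")
                seen.add(m.sample_id)
        ids = [s.sample_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicated sample_id {dup!r} among spectra")
        for s in self.spectra:
            if s.sample_id not in meta_by_id:
                raise ValueError(f"missing metadata row for sample {s.sample_id!r}")
        if self.spectra:
            grid = self.spectra[0].ppm
            for s in self.spectra[1:]:
                if s.ppm.shape != grid.shape or not np.allclose(s.ppm, grid, rtol=0, atol=1e-12):
                    raise ValueError(f"sample {s.sample_id!r} is not on the shared ppm grid")
        self.meta = {i: meta_by_id[i] for i in ids}

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.spectra]

    @property
    def ppm(self) -> np.ndarray:
        if not self.spectra:
            return np.empty(0)
        return self.spectra[0].ppm

    def labels(self) -> list[str]:
        return [self.meta[i].label_str for i in self.sample_ids]

    def subset(self, sample_ids: Sequence[str]) -> "SpectraSet":
        wanted = set(sample_ids)
        spectra = [s for s in self.spectra if s.sample_id in wanted]
        return SpectraSet(spectra, [self.meta[s.sample_id] for s in spectra])

    def meta_frame(self) -> pd.DataFrame:
        rows = []
        for sid in self.sample_ids:
            m = self.meta[sid]
            rows.append({
                "sample_id": m.sample_id,
                "class_label": m.label_str,
                "field_mhz": m.field_mhz,
                "experiment": m.experiment,
                "mixture_fraction": m.mixture_fraction,
                "extra_json": json.dumps(m.extra, sort_keys=True) if m.extra else "{}",
            })
        return pd.DataFrame(rows, columns=list(META_COLUMNS))


@dataclass
class FeatureMatrix:
    """Samples x ppm-buckets table; the input to every model.

    ``bucket_edges`` holds ``(upper, lower)`` ppm pairs, half-open on the
    descending axis; columns are ordered by descending bucket center.
    """

    values: np.ndarray
    bucket_centers: np.ndarray
    bucket_edges: np.ndarray
    sample_ids: list[str]
    normalization_state: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.bucket_centers = np.asarray(self.bucket_centers, dtype=float)
        self.bucket_edges = np.asarray(self.bucket_edges, dtype=float).reshape(-1, 2)
        self.sample_ids = list(self.sample_ids)
        if self.normalization_state not in NORMALIZATION_STATES:
            raise ValueError(f"normalization_state {self.normalization_state!r} "
                             f"not in {NORMALIZATION_STATES}")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if self.bucket_centers.size != p or self.bucket_edges.shape[0] != p:
            raise ValueError("bucket axis does not match column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")
        if p >= 2:
            if not np.all(np.diff(self.bucket_centers) < 0):
                raise ValueError("bucket centers must be strictly descending")
            # edges stored (upper, lower); adjacent buckets must not overlap
            if np.any(self.bucket_edges[:, 0] <= self.bucket_edges[:, 1]):
                raise ValueError("each bucket needs upper > lower edge")
            if np.any(self.bucket_edges[1:, 0] > self.bucket_edges[:-1, 1] + 1e-12):
                raise ValueError("bucket edges overlap")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, state: str | None = None) -> "FeatureMatrix":
        return FeatureMatrix(values, self.bucket_centers.copy(), self.bucket_edges.copy(),
                             list(self.sample_ids),
                             self.normalization_state if state is None else state)

    def rows(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        idx = [index[s] for s in sample_ids]
        return FeatureMatrix(self.values[idx], self.bucket_centers.copy(),
                             self.bucket_edges.copy(), list(sample_ids),
                             self.normalization_state)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{c:.4f}" for c in self.bucket_centers]
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)


def _parse_label(label: str) -> str | tuple[str, str]:
    if "+" in label:
        a, b = label.split("+", 1)
        return tuple(sorted((a, b)))  # type: ignore[return-value]
    return label


def read_spectra(table_path: str | Path, meta_path: str | Path) -> SpectraSet:
    """Load a ppm-by-sample intensity table and its metadata table.

    Ascending input axes are accepted and reversed to the descending
    convention with intensities re-ordered accordingly.
    """
    table = pd.read_csv(table_path)
    if table.shape[1] < 1 or table.columns[0] != "ppm":
        raise ValueError(f"{table_path}: first column must be named 'ppm'")
    ppm = pd.to_numeric(table["ppm"], errors="coerce").to_numpy()
    if np.any(~np.isfinite(ppm)):
        bad = table["ppm"][~np.isfinite(ppm)].iloc[0]
        raise ValueError(f"{table_path}: non-numeric ppm value {bad!r}")
    cols = list(table.columns[1:])
    if len(set(cols)) != len(cols):
        dup = next(c for c in cols if cols.count(c) > 1)
        raise ValueError(f"{table_path}: duplicated sample_id {dup!r}")
    if ppm.size >= 2 and ppm[0] < ppm[-1]:
        table = table.iloc[::-1].reset_index(drop=True)
        ppm = ppm[::-1]

    meta_df = pd.read_csv(meta_path, dtype={"sample_id": str})
    for col in ("sample_id", "class_label", "field_mhz", "experiment"):
        if col not in meta_df.columns:
            raise ValueError(f"{meta_path}: missing required column {col!r}")
    metas = []
    for _, row in meta_df.iterrows():
        frac = row.get("mixture_fraction")
        frac = None if frac is None or (isinstance(frac, float) and np.isnan(frac)) else float(frac)
        extra_raw = row.get("extra_json", "{}")
        extra = json.loads(extra_raw) if isinstance(extra_raw, str) and extra_raw.strip() else {}
        metas.append(SampleMeta(
            sample_id=str(row["sample_id"]),
            class_label=_parse_label(str(row["class_label"])),
            field_mhz=float(row["field_mhz"]),
            experiment=str(row["experiment"]),
            mixture_fraction=frac,
            extra=extra,
        ))
    spectra = [Spectrum(ppm.copy(), table[c].to_numpy(dtype=float), c) for c in cols]
    return SpectraSet(spectra, metas)


def write_spectra(spectra_set: SpectraSet, table_path: str | Path,
                  meta_path: str | Path) -> None:
    """Write a SpectraSet as spectra.csv + meta.csv (round-trip safe)."""
    data = {"ppm": spectra_set.ppm}
    for s in spectra_set:
        data[s.sample_id] = s.intensities
    pd.DataFrame(data).to_csv(table_path, index=False, float_format="%.17g")
    spectra_set.meta_frame().to_csv(meta_path, index=False, float_format="%.17g")


_FM_MARKERS = ("center", "edge_upper", "edge_lower")


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Serialize a FeatureMatrix: centers/edges header rows, then samples."""
    with open(path, "w") as fh:
        fh.write(f"# normalization_state: {matrix.normalization_state}\n")
        p = matrix.n_features
        header = ["row"] + [f"b{i}" for i in range(p)]
        fh.write(",".join(header) + "\n")
        for name, vals in zip(_FM_MARKERS,
                              (matrix.bucket_centers, matrix.bucket_edges[:, 0],
                               matrix.bucket_edges[:, 1])):
            fh.write(name + "," + ",".join(f"{v:.17g}" for v in vals) + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.values):
            fh.write(str(sid) + "," + ",".join(f"{v:.17g}" for v in row) + "\n")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    """Read a feature matrix written by :func:`write_feature_matrix`.

    Shuffled columns are restored to descending-ppm order; overlapping edges
    or an unknown normalization state raise.
    """
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# normalization_state:"):
            raise ValueError(f"{path}: missing normalization_state header")
        state = first.split(":", 1)[1].strip()
        body = pd.read_csv(fh, index_col=0)
    if state not in NORMALIZATION_STATES:
        raise ValueError(f"{path}: unknown normalization_state {state!r}")
    for marker in _FM_MARKERS:
        if marker not in body.index:
            raise ValueError(f"{path}: missing {marker!r} row")
    centers = body.loc["center"].to_numpy(dtype=float)
    uppers = body.loc["edge_upper"].to_numpy(dtype=float)
    lowers = body.loc["edge_lower"].to_numpy(dtype=float)
    sample_rows = [i for i in body.index if i not in _FM_MARKERS]
    values = body.loc[sample_rows].to_numpy(dtype=float)
    order = np.argsort(-centers, kind="stable")
    return FeatureMatrix(values[:, order], centers[order],
                         np.column_stack([uppers[order], lowers[order]]),
                         [str(s) for s in sample_rows], state)
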