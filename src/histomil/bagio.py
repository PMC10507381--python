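"""Cohort manifests, tile-embedding bags, and their on-disk HDF5 store.

A *bag* is the multiple-instance-learning unit: the n x d matrix of tile
embeddings from one slide (or from all slides of one patient), together
with the tile grid coordinates needed to paint heatmaps back onto the
slide. Bags are stored one HDF5 group per slide; the patient-to-slide
mapping lives only in the manifest so a store can be reused across label
targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TileBag",
    "CohortManifest",
    "BagStore",
    "read_manifest",
    "write_bag",
    "read_bag",
    "assemble_patient_bag",
]


@dataclass
class TileBag:
    """One bag: n tile embeddings with grid coordinates and provenance."""

    embeddings: np.ndarray          # (n, d_in) float32
    coords: np.ndarray              # (n, 2) int32, (col, row) in tile units
    patient_id: str = ""
    slide_ids: list[str] = field(default_factory=list)
    mpp: float = 0.5
    tile_size_px: int = 512
    featurizer: str = "unknown"
    witness_mask: np.ndarray | None = None  # ground truth for synthetic bags

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int32)
        if self.embeddings.ndim != 2 or self.embeddings.shape[0] < 1:
            raise ValueError("embeddings must be a non-empty n x d matrix")
        if not np.isfinite(self.embeddings).all():
            raise ValueError("embeddings contain non-finite values")
        if self.coords.shape != (self.embeddings.shape[0], 2):
            raise ValueError("coords must have shape n x 2")

    @property
    def n_tiles(self) -> int:
        return self.embeddings.shape[0]

    @property
    def d_in(self) -> int:
        return self.embeddings.shape[1]


class CohortManifest:
    """Validated table of patients: ids, slide paths, labels, cohorts.

    One row per patient; `slide_refs` lists all slides of that patient.
    Rows with a missing label are retained but excluded from
    `usable_for_training`.
    """

    REQUIRED = ("patient_id", "slide_path", "label", "cohort")

    def __init__(self, table: pd.DataFrame):
        if "patient_id" not in table.columns:
            raise ValueError("manifest lacks a patient_id column")
        if table["patient_id"].duplicated().any():
            dup = table.loc[table["patient_id"].duplicated(), "patient_id"]
            raise ValueError(f"duplicate patient_id rows: {sorted(set(dup))}")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.table["patient_id"])

    @property
    def labels(self) -> pd.Series:
        return self.table.set_index("patient_id")["label"]

    def slide_refs(self, patient_id: str) -> list[str]:
        row = self.table.loc[self.table["patient_id"] == patient_id]
        if row.empty:
            raise KeyError(f"unknown patient_id {patient_id!r}")
        return list(row.iloc[0]["slide_refs"])

    def usable_for_training(self) -> "CohortManifest":
        """Patients whose label is present and binary."""
        ok = self.table["label"].notna()
        return CohortManifest(self.table.loc[ok].reset_index(drop=True))

    def subset(self, patient_ids: Iterable[str]) -> "CohortManifest":
        wanted = set(patient_ids)
        keep = self.table["patient_id"].isin(wanted)
        return CohortManifest(self.table.loc[keep].reset_index(drop=True))


def read_manifest(path, label_column: str = "label",
                  label_map: Mapping[str, int] | None = None,
                  sep: str | None = None) -> CohortManifest:
    """Read a delimited cohort manifest.

    The file needs columns patient_id, slide_path, `label_column`, cohort;
    multiple rows with the same patient_id encode multiple slides of one
    patient and are grouped into a single manifest row. `label_map`
    translates string labels (e.g. {"MSI-high": 1, "MSS": 0}) to {0,1}.
    An unknown label value, or a patient whose rows disagree on label or
    cohort, is a hard error naming the offending row.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=sep, dtype={"patient_id": str})
    missing = [c for c in ("patient_id", "slide_path", "cohort")
               if c not in raw.columns]
    if missing:
        raise ValueError(f"manifest lacks required columns: {missing}")
    if label_column not in raw.columns:
        raise ValueError(f"manifest lacks label column {label_column!r}")

    def encode(v, row_idx):
        if pd.isna(v):
            return np.nan
        if label_map is not None:
            if v not in label_map:
                raise ValueError(
                    f"row {row_idx}: label {v!r} not in declared mapping")
            return int(label_map[v])
        try:
            iv = int(v)
        except (TypeError, ValueError):
            raise ValueError(
                f"row {row_idx}: label {v!r} is not binary and no "
                "mapping was declared") from None
        if iv not in (0, 1):
            raise ValueError(f"row {row_idx}: label {v!r} not in {{0,1}}")
        return iv

    raw = raw.copy()
    raw["label"] = [encode(v, i) for i, v in enumerate(raw[label_column])]

    dup_slides = raw.duplicated(subset=["patient_id", "slide_path"])
    if dup_slides.any():
        bad = raw.loc[dup_slides, ["patient_id", "slide_path"]]
        raise ValueError(f"duplicate patient/slide rows:\n{bad}")
    # a slide path may appear under only one patient
    multi_owner = raw.groupby("slide_path")["patient_id"].nunique()
    if (multi_owner > 1).any():
        bad = multi_owner[multi_owner > 1].index.tolist()
        raise ValueError(f"slides listed under multiple patients: {bad}")

    rows = []
    extra_cols = [c for c in raw.columns
                  if c not in ("patient_id", "slide_path", "label",
                               label_column)]
    for pid, grp in raw.groupby("patient_id", sort=True):
        labels = grp["label"].dropna().unique()
        if len(labels) > 1:
            raise ValueError(f"patient {pid!r}: conflicting labels {labels}")
        row = {
            "patient_id": pid,
            "slide_refs": list(grp["slide_path"]),
            "label": labels[0] if len(labels) else np.nan,
        }
        for c in extra_cols:
            vals = grp[c].unique()
            if len(vals) > 1:
                raise ValueError(
                    f"patient {pid!r}: conflicting values in column {c!r}")
            row[c] = vals[0]
        rows.append(row)
    return CohortManifest(pd.DataFrame(rows))


class BagStore:
    """HDF5 container holding one group per slide.

    Each group has datasets "embeddings" (float32 n x d), "coords"
    (int32 n x 2) and attributes mpp, tile_size_px, featurizer,
    patient_id. Embeddings round-trip bit-exactly.
    """

    def __init__(self, path):
        self.path = Path(path)

    def slide_ids(self) -> list[str]:
        if not self.path.exists():
            return []
        with h5py.File(self.path, "r") as f:
            return sorted(f.keys())

    def write(self, bag: TileBag, slide_id: str | None = None,
              overwrite: bool = False) -> None:
        if slide_id is None:
            if len(bag.slide_ids) != 1:
                raise ValueError("slide_id required for multi-slide bags")
            slide_id = bag.slide_ids[0]
        with h5py.File(self.path, "a") as f:
            if slide_id in f:
                if not overwrite:
                    raise ValueError(f"slide {slide_id!r} already in store")
                del f[slide_id]
            g = f.create_group(slide_id)
            g.create_dataset("embeddings", data=bag.embeddings)
            g.create_dataset("coords", data=bag.coords)
            if bag.witness_mask is not None:
                g.create_dataset("witness_mask",
                                 data=bag.witness_mask.astype(np.uint8))
            g.attrs["mpp"] = float(bag.mpp)
            g.attrs["tile_size_px"] = int(bag.tile_size_px)
            g.attrs["featurizer"] = bag.featurizer
            g.attrs["patient_id"] = bag.patient_id

    def read(self, slide_id: str) -> TileBag:
        with h5py.File(self.path, "r") as f:
            if slide_id not in f:
                raise KeyError(f"slide {slide_id!r} not found in "
                               f"{self.path}")
            g = f[slide_id]
            witness = (np.asarray(g["witness_mask"]).astype(bool)
                       if "witness_mask" in g else None)
            return TileBag(
                embeddings=np.asarray(g["embeddings"]),
                coords=np.asarray(g["coords"]),
                patient_id=str(g.attrs.get("patient_id", "")),
                slide_ids=[slide_id],
                mpp=float(g.attrs["mpp"]),
                tile_size_px=int(g.attrs["tile_size_px"]),
                featurizer=str(g.attrs["featurizer"]),
                witness_mask=witness,
            )


def write_bag(store: BagStore, bag: TileBag,
              slide_id: str | None = None, overwrite: bool = False) -> None:
    store.write(bag, slide_id=slide_id, overwrite=overwrite)


def read_bag(store: BagStore, slide_id: str) -> TileBag:
    return store.read(slide_id)


def assemble_patient_bag(manifest: CohortManifest, store: BagStore,
                         patient_id: str) -> TileBag:
    """Pool all of a patient's slides into one bag.

    Tiles are ordered by the manifest's slide order and, within a slide,
    row-major by grid coordinate, so assembly is deterministic regardless
    of the container's iteration order.
    """
    slide_refs = manifest.slide_refs(patient_id)
    if not slide_refs:
        raise ValueError(f"no slides listed for patient {patient_id!r}")
    parts: list[TileBag] = []
    for ref in slide_refs:
        sid = Path(str(ref)).stem
        bag = store.read(sid)
        order = np.lexsort((bag.coords[:, 0], bag.coords[:, 1]))
        parts.append(TileBag(
            embeddings=bag.embeddings[order],
            coords=bag.coords[order],
            patient_id=patient_id,
            slide_ids=[sid],
            mpp=bag.mpp,
            tile_size_px=bag.tile_size_px,
            featurizer=bag.featurizer,
            witness_mask=(bag.witness_mask[order]
                          if bag.witness_mask is not None else None),
        ))
    witness = (np.concatenate([p.witness_mask for p in parts])
               if all(p.witness_mask is not None for p in parts) else None)
    return TileBag(
        embeddings=np.concatenate([p.embeddings for p in parts]),
        coords=np.concatenate([p.coords for p in parts]),
        patient_id=patient_id,
        slide_ids=[p.slide_ids[0] for p in parts],
        mpp=parts[0].mpp,
        tile_size_px=parts[0].tile_size_px,
        featurizer=parts[0].featurizer,
        witness_mask=witness,
    )
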