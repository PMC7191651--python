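"""Core containers for emotion-rating tables, parcellations and fMRI responses.

The analyses in this package operate on three aligned objects:

* an :class:`EmotionScoreMatrix` — per-video emotion ratings, split into
  *category* scores (rater endorsement proportions in [0, 1], typically
  sparse) and *affective dimension* scores (Likert ratings on [1, 9] with
  5 as the neutral point);
* a :class:`RegionParcellation` — a mapping from voxels to named brain
  regions (by default 180 cortical areas per hemisphere plus 10
  subcortical structures, 370 regions in total);
* one :class:`ResponseDataset` per subject — a videos x voxels response
  matrix carrying its parcellation.

Everything is stored row-aligned to a shared ordered list of video ids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EmotionScoreMatrix",
    "RegionParcellation",
    "ResponseDataset",
    "default_region_registry",
    "make_parcellation",
    "save_scores",
    "load_scores",
    "save_parcellation",
    "load_parcellation",
    "save_responses",
    "load_responses",
]

SUBCORTICAL_REGIONS = (
    "amygdala",
    "hippocampus",
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "nucleus_accumbens",
    "hypothalamus",
    "brainstem",
    "cerebellum",
)


@dataclass
class EmotionScoreMatrix:
    """Per-video emotion ratings: categories in [0, 1], dimensions in [1, 9]."""

    video_ids: list[str]
    category_scores: np.ndarray
    dimension_scores: np.ndarray
    category_names: list[str]
    dimension_names: list[str]

    def __post_init__(self) -> None:
        self.category_scores = np.asarray(self.category_scores, dtype=float)
        self.dimension_scores = np.asarray(self.dimension_scores, dtype=float)
        n = len(self.video_ids)
        if self.category_scores.shape != (n, len(self.category_names)):
            raise ValueError("category_scores shape does not match ids/names")
        if self.dimension_scores.shape != (n, len(self.dimension_names)):
            raise ValueError("dimension_scores shape does not match ids/names")
        if np.isnan(self.category_scores).any() or np.isnan(self.dimension_scores).any():
            raise ValueError("scores must not contain missing values")
        if self.category_scores.size and (
            self.category_scores.min() < 0 or self.category_scores.max() > 1
        ):
            raise ValueError("category scores must lie in [0, 1]")
        if self.dimension_scores.size and (
            self.dimension_scores.min() < 1 or self.dimension_scores.max() > 9
        ):
            raise ValueError("dimension scores must lie in [1, 9]")

    @property
    def n_videos(self) -> int:
        return len(self.video_ids)

    @property
    def n_categories(self) -> int:
        return len(self.category_names)

    @property
    def n_dimensions(self) -> int:
        return len(self.dimension_names)

    @property
    def emotion_names(self) -> list[str]:
        """All emotion labels, categories first then dimensions."""
        return list(self.category_names) + list(self.dimension_names)

    def matrix(self) -> np.ndarray:
        """Full videos x (n_cat + n_dim) score matrix, categories first."""
        return np.hstack([self.category_scores, self.dimension_scores])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix(), index=self.video_ids, columns=self.emotion_names
        )


@dataclass
class RegionParcellation:
    """Voxel -> region assignment plus a region registry.

    ``registry`` is a DataFrame indexed by region name with columns
    ``class`` ("cortical" or "subcortical") and ``hemisphere``
    ("L", "R" or "both").
    """

    voxel_ids: list[str]
    region_labels: np.ndarray
    registry: pd.DataFrame

    def __post_init__(self) -> None:
        self.region_labels = np.asarray(self.region_labels, dtype=object)
        if len(self.voxel_ids) != len(self.region_labels):
            raise ValueError("one region label per voxel required")
        known = set(self.registry.index)
        unknown = set(self.region_labels) - known
        if unknown:
            raise ValueError(f"voxels mapped to unregistered regions: {sorted(unknown)[:5]}")

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ids)

    @property
    def region_names(self) -> list[str]:
        return list(self.registry.index)

    @property
    def n_regions(self) -> int:
        return len(self.registry)

    def voxels_of(self, region: str) -> np.ndarray:
        """Indices of the voxels belonging to ``region`` (registry order)."""
        return np.flatnonzero(self.region_labels == region)


@dataclass
class ResponseDataset:
    """Videos x voxels responses for one subject, with its parcellation."""

    subject_id: str
    responses: np.ndarray
    parcellation: RegionParcellation
    video_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.shape[0] != len(self.video_ids):
            raise ValueError("response rows must match video_ids")
        if self.responses.shape[1] != self.parcellation.n_voxels:
            raise ValueError("response columns must match parcellation voxel count")

    @property
    def n_videos(self) -> int:
        return len(self.video_ids)

    @property
    def n_voxels(self) -> int:
        return self.responses.shape[1]

    def region_responses(self, region: str) -> np.ndarray:
        return self.responses[:, self.parcellation.voxels_of(region)]


def default_region_registry() -> pd.DataFrame:
    """The default registry: 180 cortical areas x 2 hemispheres + 10 subcortical.

    Cortical parcels are named ``{L,R}_area{001..180}`` as generic
    stand-ins for an HCP-style cortical parcellation; the 10 subcortical
    entries use anatomical names. 370 regions in total.
    """
    rows = []
    for hemi in ("L", "R"):
        for i in range(1, 181):
            rows.append((f"{hemi}_area{i:03d}", "cortical", hemi))
    for name in SUBCORTICAL_REGIONS:
        rows.append((name, "subcortical", "both"))
    reg = pd.DataFrame(rows, columns=["region", "class", "hemisphere"])
    return reg.set_index("region")


def make_parcellation(
    registry: pd.DataFrame | None = None,
    voxels_per_region: int = 30,
    region_names: list[str] | None = None,
) -> RegionParcellation:
    """Build a parcellation with a fixed number of voxels per region.

    With no arguments this yields the default 370-region registry. Pass
    ``region_names`` for small custom registries (all marked cortical/L
    unless a full ``registry`` frame is given).
    """
    if voxels_per_region < 1:
        raise ValueError("voxels_per_region must be positive")
    if registry is None:
        if region_names is not None:
            registry = pd.DataFrame(
                {"class": "cortical", "hemisphere": "L"},
                index=pd.Index(region_names, name="region"),
            )
        else:
            registry = default_region_registry()
    labels: list[str] = []
    voxel_ids: list[str] = []
    for region in registry.index:
        for j in range(voxels_per_region):
            voxel_ids.append(f"{region}.v{j:03d}")
            labels.append(region)
    return RegionParcellation(voxel_ids, np.array(labels, dtype=object), registry)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_scores(scores: EmotionScoreMatrix, path: str | Path) -> None:
    """Write scores as CSV plus a JSON sidecar marking column types."""
    path = Path(path)
    scores.to_frame().rename_axis("video_id").to_csv(path)
    meta = {
        "category_columns": list(scores.category_names),
        "dimension_columns": list(scores.dimension_names),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_scores(path: str | Path) -> EmotionScoreMatrix:
    path = Path(path)
    frame = pd.read_csv(path, index_col="video_id")
    meta = json.loads(_sidecar(path).read_text())
    cats, dims = meta["category_columns"], meta["dimension_columns"]
    return EmotionScoreMatrix(
        video_ids=[str(v) for v in frame.index],
        category_scores=frame[cats].to_numpy(),
        dimension_scores=frame[dims].to_numpy(),
        category_names=cats,
        dimension_names=dims,
    )


def save_parcellation(parc: RegionParcellation, path: str | Path) -> None:
    path = Path(path)
    table = pd.DataFrame(
        {
            "voxel_id": parc.voxel_ids,
            "region": parc.region_labels,
            "class": [parc.registry.loc[r, "class"] for r in parc.region_labels],
            "hemisphere": [parc.registry.loc[r, "hemisphere"] for r in parc.region_labels],
        }
    )
    table.to_csv(path, sep="\t", index=False)
    reg = parc.registry.reset_index().to_dict(orient="list")
    _sidecar(path).write_text(json.dumps(reg, indent=1))


def load_parcellation(path: str | Path) -> RegionParcellation:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    reg = json.loads(_sidecar(path).read_text())
    registry = pd.DataFrame(reg).set_index("region")
    return RegionParcellation(
        voxel_ids=[str(v) for v in table["voxel_id"]],
        region_labels=table["region"].to_numpy(dtype=object),
        registry=registry,
    )


def save_responses(ds: ResponseDataset, path: str | Path, text: bool = False) -> None:
    """Write a response dataset: ``.npz`` matrix + JSON sidecar.

    With ``text=True`` the matrix is written as TSV instead (small
    fixtures only).
    """
    path = Path(path)
    if text:
        pd.DataFrame(ds.responses, index=ds.video_ids, columns=ds.parcellation.voxel_ids).rename_axis(
            "video_id"
        ).to_csv(path, sep="\t")
    else:
        np.savez_compressed(path, responses=ds.responses)
    meta = {
        "subject_id": ds.subject_id,
        "video_ids": list(ds.video_ids),
        "voxel_ids": list(ds.parcellation.voxel_ids),
        "region_labels": [str(r) for r in ds.parcellation.region_labels],
        "registry": ds.parcellation.registry.reset_index().to_dict(orient="list"),
        "text": text,
    }
    _sidecar(path).write_text(json.dumps(meta))


def load_responses(path: str | Path) -> ResponseDataset:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("text", False):
        responses = pd.read_csv(path, sep="\t", index_col="video_id").to_numpy()
    else:
        candidate = path if path.exists() else path.with_suffix(path.suffix + ".npz")
        with np.load(candidate) as payload:
            responses = payload["responses"]
    registry = pd.DataFrame(meta["registry"]).set_index("region")
    parc = RegionParcellation(
        voxel_ids=meta["voxel_ids"],
        region_labels=np.array(meta["region_labels"], dtype=object),
        registry=registry,
    )
    return ResponseDataset(
        subject_id=meta["subject_id"],
        responses=responses,
        parcellation=parc,
        video_ids=meta["video_ids"],
    )
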