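"""Nucleus gallery input/output and elementary per-nucleus bookkeeping.

A gallery is one directory per patient holding a 16-bit greyscale TIFF per
segmented nucleus together with a binary mask image of identical basename and
``_mask`` suffix, plus a per-patient ``manifest.csv``.  A cohort adds a
case-table CSV (columns exactly ``patient_id,label,split``) and a
``cohort.json`` with acquisition metadata (grey depth, background intensity).

Grey-level convention used throughout the package: a larger pixel value means
more transmitted light, i.e. brighter glass and *less* DNA.  Optical density
is therefore ``log10(background / pixel)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

LABELS = ("nondysplastic", "dysplastic")
SPLITS = ("train", "test")

#: pixel-area interval edges: A0 < 1000 px, A1 = 1000-1999, ..., A10 >= 10000
AREA_GROUP_WIDTH = 1000
N_AREA_GROUPS = 11


@dataclass
class NucleusImage:
    """One segmented nucleus: grey-level pixels plus its binary mask.

    Parameters
    ----------
    pixels : ndarray of int
        Transmitted-light grey levels in ``[0, grey_depth - 1]``.
    mask : ndarray of bool
        Same shape as ``pixels``; True on nuclear pixels.
    patient_id, nucleus_id : str
        Identifiers used for grouping and deterministic ordering.
    """

    pixels: np.ndarray
    mask: np.ndarray
    patient_id: str = ""
    nucleus_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.pixels.shape != self.mask.shape:
            raise ValueError(
                f"nucleus {self.nucleus_id!r}: pixel shape {self.pixels.shape} "
                f"!= mask shape {self.mask.shape}"
            )

    @property
    def area(self) -> int:
        """Number of mask-true pixels."""
        return int(self.mask.sum())

    def validate(self, grey_depth: int | None = None) -> None:
        if self.area == 0:
            raise ValueError(f"nucleus {self.nucleus_id!r}: empty mask")
        if self.pixels.min() < 0:
            raise ValueError(f"nucleus {self.nucleus_id!r}: negative grey level")
        if grey_depth is not None and self.pixels.max() >= grey_depth:
            raise ValueError(
                f"nucleus {self.nucleus_id!r}: grey level "
                f"{int(self.pixels.max())} >= grey depth {grey_depth}"
            )


def requantise(nucleus: NucleusImage, from_levels: int, to_levels: int) -> NucleusImage:
    """Reduce the grey-level depth by linear floor binning.

    Each pixel maps to ``floor(pixel * to_levels / from_levels)``; the mask and
    area are unchanged.  Linear binning preserves the ordering of optical
    densities.
    """
    if from_levels < to_levels:
        raise ValueError(f"cannot requantise {from_levels} -> {to_levels} levels")
    px = nucleus.pixels
    if px.max() >= from_levels:
        raise ValueError(
            f"nucleus {nucleus.nucleus_id!r}: grey level {int(px.max())} "
            f">= from_levels {from_levels}"
        )
    out = (px.astype(np.int64) * to_levels) // from_levels
    return NucleusImage(
        pixels=out.astype(px.dtype),
        mask=nucleus.mask,
        patient_id=nucleus.patient_id,
        nucleus_id=nucleus.nucleus_id,
    )


def area_group(area: int) -> int:
    """Map a nuclear pixel area to its interval index A0..A10.

    A0 collects areas below 1000 px, A1 covers 1000-1999 px and so on;
    every area of 10000 px or more falls in A10, so the mapping is total
    and monotone.
    """
    if area <= 0:
        raise ValueError(f"non-positive nuclear area: {area}")
    return min(int(area) // AREA_GROUP_WIDTH, N_AREA_GROUPS - 1)


# ---------------------------------------------------------------------------
# gallery read/write


def write_gallery(nuclei: list[NucleusImage], path: str | Path) -> None:
    """Write one TIFF + mask pair per nucleus into ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for nuc in nuclei:
        tifffile.imwrite(path / f"{nuc.nucleus_id}.tif", nuc.pixels.astype(np.uint16))
        tifffile.imwrite(
            path / f"{nuc.nucleus_id}_mask.tif", nuc.mask.astype(np.uint8)
        )


def load_gallery(path: str | Path, patient_id: str | None = None) -> list[NucleusImage]:
    """Load every image/mask pair in a gallery directory.

    Nuclei are returned in deterministic order by nucleus id.  A missing mask
    raises; an all-false mask skips the nucleus with a warning.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"gallery directory not found: {path}")
    if patient_id is None:
        patient_id = path.name
    nuclei: list[NucleusImage] = []
    images = sorted(
        p for p in path.glob("*.tif") if not p.stem.endswith("_mask")
    )
    for img_path in images:
        mask_path = img_path.with_name(img_path.stem + "_mask.tif")
        if not mask_path.exists():
            raise FileNotFoundError(f"missing mask for nucleus image {img_path}")
        pixels = tifffile.imread(img_path)
        mask = tifffile.imread(mask_path) > 0
        nuc = NucleusImage(
            pixels=pixels, mask=mask, patient_id=patient_id, nucleus_id=img_path.stem
        )
        if nuc.area == 0:
            warnings.warn(
                f"nucleus {img_path.stem!r} in {path.name!r} has an empty mask; skipped",
                stacklevel=2,
            )
            continue
        nuc.validate()
        nuclei.append(nuc)
    return nuclei


# ---------------------------------------------------------------------------
# case tables and cohorts


def validate_case_table(cases: pd.DataFrame) -> pd.DataFrame:
    required = ["patient_id", "label", "split"]
    missing = [c for c in required if c not in cases.columns]
    if missing:
        raise ValueError(f"case table missing columns: {missing}")
    if cases["patient_id"].duplicated().any():
        dup = cases.loc[cases["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient ids in case table: {dup}")
    bad = set(cases["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"unknown labels in case table: {sorted(bad)}")
    bad = set(cases["split"]) - set(SPLITS)
    if bad:
        raise ValueError(f"unknown splits in case table: {sorted(bad)}")
    return cases[required]


def load_case_table(path: str | Path) -> pd.DataFrame:
    return validate_case_table(pd.read_csv(path, dtype=str))


def write_case_table(cases: pd.DataFrame, path: str | Path) -> None:
    validate_case_table(cases).to_csv(path, index=False)


@dataclass
class Cohort:
    """An in-memory cohort: per-patient galleries plus the case table.

    ``meta`` carries acquisition metadata (``grey_depth``,
    ``background_intensity``, ``iod_per_c``, ``seed``); ``manifests`` the
    per-patient nucleus tables (nucleus_id, area_px, true_c when synthetic).
    """

    patients: dict[str, list[NucleusImage]]
    cases: pd.DataFrame
    meta: dict
    manifests: dict[str, pd.DataFrame] = field(default_factory=dict)

    def nuclei(self) -> list[NucleusImage]:
        out: list[NucleusImage] = []
        for pid in self.cases["patient_id"]:
            out.extend(self.patients[pid])
        return out


def write_cohort(cohort: Cohort, root: str | Path) -> None:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    write_case_table(cohort.cases, root / "case_table.csv")
    (root / "cohort.json").write_text(json.dumps(cohort.meta, indent=2, sort_keys=True))
    galleries = root / "galleries"
    for pid, nuclei in cohort.patients.items():
        write_gallery(nuclei, galleries / pid)
        manifest = cohort.manifests.get(pid)
        if manifest is not None:
            manifest.to_csv(galleries / pid / "manifest.csv", index=False)


def load_cohort(root: str | Path) -> Cohort:
    root = Path(root)
    cases = load_case_table(root / "case_table.csv")
    meta_path = root / "cohort.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    patients = {}
    manifests = {}
    for pid in cases["patient_id"]:
        gdir = root / "galleries" / pid
        patients[pid] = load_gallery(gdir, patient_id=pid)
        mpath = gdir / "manifest.csv"
        if mpath.exists():
            manifests[pid] = pd.read_csv(mpath)
    return Cohort(patients=patients, cases=cases, meta=meta, manifests=manifests)
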