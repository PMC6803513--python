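"""Integer label volumes with name/hemisphere lookup, plus a toy atlas.

The toy atlas lays out rectangular blocks standing in for the white-matter
tracts a standard DTI label atlas provides (corpus callosum subdivisions,
corona radiata, internal/external capsule, superior longitudinal
fasciculus, fornix), so region summaries and planted-effect simulations
can be tested without the real atlas file.  A real atlas may be supplied
as a NIfTI integer volume plus a 3-column CSV lookup (id, name,
hemisphere); it is never bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right", "midline")


@dataclass
class LabelVolume:
    """3D integer labels (0 = unlabeled) with an id -> (name, hemisphere) lookup."""

    data: np.ndarray
    lookup: dict[int, tuple[str, str]] = field(default_factory=dict)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        present = set(np.unique(self.data)) - {0}
        missing = present - set(self.lookup)
        if missing:
            raise ValueError(f"labels present in volume but not in lookup: {sorted(missing)}")
        for lid, (name, hemi) in self.lookup.items():
            if hemi not in HEMISPHERES:
                raise ValueError(f"label {lid} ({name}): bad hemisphere {hemi!r}")

    def label_of(self, name: str) -> int:
        hits = [lid for lid, (n, _) in self.lookup.items() if n == name]
        if len(hits) != 1:
            raise KeyError(f"region name {name!r} resolves to {len(hits)} labels")
        return hits[0]

    def region_mask(self, name: str) -> np.ndarray:
        return self.data == self.label_of(name)

    def lookup_frame(self) -> pd.DataFrame:
        rows = [(lid, n, h) for lid, (n, h) in sorted(self.lookup.items())]
        return pd.DataFrame(rows, columns=["label_id", "name", "hemisphere"])


#: Default toy layout: name, hemisphere, half-open block (x0,x1, y0,y1, z0,z1)
#: on a 24 x 40 x 12 grid.  Left hemisphere occupies low x, right high x,
#: midline structures straddle the center.
DEFAULT_TOY_SHAPE = (24, 40, 12)


def default_toy_regions() -> list[dict]:
    """Block layout naming stand-ins for the commonly reported tracts."""
    b = lambda name, hemi, block: {"name": name, "hemisphere": hemi, "block": block}
    return [
        b("genu_of_corpus_callosum", "midline", (10, 14, 34, 38, 4, 8)),
        b("body_of_corpus_callosum", "midline", (10, 14, 27, 31, 4, 8)),
        b("fornix", "midline", (10, 14, 20, 24, 4, 8)),
        b("anterior_corona_radiata_l", "left", (3, 7, 30, 34, 4, 8)),
        b("anterior_corona_radiata_r", "right", (17, 21, 30, 34, 4, 8)),
        b("superior_corona_radiata_l", "left", (3, 7, 24, 28, 4, 8)),
        b("superior_corona_radiata_r", "right", (17, 21, 24, 28, 4, 8)),
        b("posterior_corona_radiata_l", "left", (3, 7, 18, 22, 4, 8)),
        b("posterior_corona_radiata_r", "right", (17, 21, 18, 22, 4, 8)),
        b("internal_capsule_l", "left", (3, 7, 12, 16, 4, 8)),
        b("internal_capsule_r", "right", (17, 21, 12, 16, 4, 8)),
        b("external_capsule_l", "left", (3, 7, 6, 10, 4, 8)),
        b("external_capsule_r", "right", (17, 21, 6, 10, 4, 8)),
        b("superior_longitudinal_fasciculus_l", "left", (3, 7, 0, 6, 4, 8)),
        b("superior_longitudinal_fasciculus_r", "right", (17, 21, 0, 6, 4, 8)),
    ]


def make_toy_atlas(
    shape: tuple[int, int, int] = DEFAULT_TOY_SHAPE,
    regions: list[dict] | None = None,
    affine: np.ndarray | None = None,
) -> LabelVolume:
    """Deterministic block-structured label volume.

    Each region dict needs ``name``, ``hemisphere`` and a half-open
    ``block`` extent (x0, x1, y0, y1, z0, z1).  Labels are assigned 1..N
    in list order.  Overlapping or out-of-bounds blocks raise.
    """
    if regions is None:
        regions = default_toy_regions()
    data = np.zeros(shape, dtype=np.int32)
    lookup: dict[int, tuple[str, str]] = {}
    for i, reg in enumerate(regions, start=1):
        x0, x1, y0, y1, z0, z1 = reg["block"]
        if not (0 <= x0 < x1 <= shape[0] and 0 <= y0 < y1 <= shape[1]
                and 0 <= z0 < z1 <= shape[2]):
            raise ValueError(f"region {reg['name']!r}: block outside shape {shape}")
        sl = (slice(x0, x1), slice(y0, y1), slice(z0, z1))
        if np.any(data[sl] != 0):
            raise ValueError(f"region {reg['name']!r} overlaps an earlier block")
        data[sl] = i
        lookup[i] = (reg["name"], reg["hemisphere"])
    return LabelVolume(data=data, lookup=lookup, affine=affine)


def read_label_volume(nifti_path, lookup_csv) -> LabelVolume:
    """Load an integer label NIfTI and its (id, name, hemisphere) CSV."""
    import nibabel as nib

    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj).astype(np.int32)
    table = pd.read_csv(lookup_csv)
    lookup = {
        int(r.label_id): (str(r.name), str(r.hemisphere))
        for r in table.itertuples(index=False)
    }
    return LabelVolume(data=data, lookup=lookup, affine=img.affine)


def write_label_volume(atlas: LabelVolume, nifti_path, lookup_csv) -> None:
    import nibabel as nib

    affine = atlas.affine if atlas.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(atlas.data.astype(np.int32), affine), str(nifti_path))
    atlas.lookup_frame().to_csv(lookup_csv, index=False)
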