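"""Synthetic multi-channel tissue images with known ground truth.

Emulates the data a padlock-probe / rolling-circle in situ mutation assay
produces: sparse diffraction-limited spots (one per detected transcript) on
an autofluorescent tissue background, imaged in a nuclear counterstain
channel plus one channel per detection probe (wild-type, mutant, optionally
a positive-control transcript). Each tumor area has its own spot density and
mutant fraction; one area may contain a sub-clonal patch with a different
mutant fraction; a configurable fraction of spots is rendered at identical
coordinates in two non-nuclear channels to mimic unspecific (multi-
wavelength) artifacts. Every rendered spot is recorded in the ground truth,
so detection, artifact exclusion and quantification are all testable against
known answers.

Spots are additive isotropic Gaussian blobs on a constant background,
followed by Poisson (or additive Gaussian) noise — the simplest model that
exercises signal/background-ratio detection. The seed fully determines the
output, bit for bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .imaging import ChannelStack
from .quantification import RegionLayout

SPOT_CLASSES = ("wildtype", "mutant", "control", "unspecific")


@dataclass
class RegionSpec:
    """One tumor area: where it is, how cellular it is, what it expresses.

    ``density`` is informative (wild-type + mutant) spots per pixel²;
    ``mutant_fraction`` the probability an informative spot is mutant.
    Geometry is a boolean ``mask`` or a ``bbox`` (row0, col0, height, width).
    """

    region_id: int
    tumor_content: float
    density: float
    mutant_fraction: float
    mask: np.ndarray | None = None
    bbox: tuple[int, int, int, int] | None = None

    def resolve_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != shape:
                raise ValueError(
                    f"region {self.region_id}: mask shape {m.shape} != image {shape}"
                )
            return m
        if self.bbox is None:
            raise ValueError(f"region {self.region_id}: neither mask nor bbox given")
        r0, c0, h, w = self.bbox
        m = np.zeros(shape, dtype=bool)
        m[r0 : r0 + h, c0 : c0 + w] = True
        return m


@dataclass
class SubcloneSpec:
    """A patch inside one area whose mutant fraction differs from its parent."""

    parent_region: int
    mutant_fraction: float
    mask: np.ndarray | None = None
    bbox: tuple[int, int, int, int] | None = None

    def resolve_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.mask is not None:
            return np.asarray(self.mask, dtype=bool)
        if self.bbox is None:
            raise ValueError("subclone: neither mask nor bbox given")
        r0, c0, h, w = self.bbox
        m = np.zeros(shape, dtype=bool)
        m[r0 : r0 + h, c0 : c0 + w] = True
        return m


@dataclass
class SimConfig:
    """Full description of one simulated acquisition.

    noise_model is ("poisson", None) — shot noise with the pixel value as
    rate — or ("gaussian", sigma) for additive noise. ``unspecific_rate`` is
    the fraction of spots rendered into two non-nuclear channels.
    ``content_field_sigma``/``content_field_amplitude`` shape the smooth
    spatial wobble added to each region's scalar tumor content so
    field-of-view gating has texture to act on.
    """

    image_shape: tuple[int, int] = (1024, 1024)
    n_z: int = 3
    channel_map: list[tuple[str, str]] = field(
        default_factory=lambda: [("DAPI", "nuclear"), ("Cy3", "wildtype"), ("FITC", "mutant")]
    )
    regions: list[RegionSpec] = field(default_factory=list)
    subclone: SubcloneSpec | None = None
    unspecific_rate: float = 0.015
    psf_sigma: float = 1.5
    spot_amplitude: float = 200.0
    background_level: float = 20.0
    noise_model: tuple[str, float | None] = ("poisson", None)
    control_density: float = 0.0
    nuclei_density: float = 1e-4
    nuclei_sigma: float = 6.0
    content_field_amplitude: float = 0.05
    content_field_sigma: float = 64.0
    seed: int = 0

    def validate(self) -> None:
        for r in self.regions:
            if not 0.0 <= r.mutant_fraction <= 1.0:
                raise ValueError(f"region {r.region_id}: mutant_fraction not in [0,1]")
            if not 0.0 <= r.tumor_content <= 1.0:
                raise ValueError(f"region {r.region_id}: tumor_content not in [0,1]")
            if r.density < 0:
                raise ValueError(f"region {r.region_id}: negative density")
        if not 0.0 <= self.unspecific_rate <= 1.0:
            raise ValueError("unspecific_rate not in [0,1]")
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region ids")
        # masks must be pairwise disjoint
        occupancy = np.zeros(self.image_shape, dtype=np.uint8)
        for r in self.regions:
            occupancy += r.resolve_mask(self.image_shape)
        if np.any(occupancy > 1):
            raise ValueError("region masks overlap")
        if self.subclone is not None:
            parents = [r for r in self.regions if r.region_id == self.subclone.parent_region]
            if not parents:
                raise ValueError(
                    f"subclone parent region {self.subclone.parent_region} not defined"
                )
            sub = self.subclone.resolve_mask(self.image_shape)
            parent_mask = parents[0].resolve_mask(self.image_shape)
            if np.any(sub & ~parent_mask):
                raise ValueError("subclone patch extends outside its parent region")
        for r in self.regions:
            # mean nearest-neighbour spacing of a 2-D Poisson process is
            # 0.5/sqrt(density); below ~2 PSF sigma spots start to merge
            if r.density > 0 and 0.5 / math.sqrt(r.density) < 2 * self.psf_sigma:
                warnings.warn(
                    f"region {r.region_id}: spot density {r.density:.2e}/px^2 gives "
                    f"expected spacing below 2*psf_sigma; resolvability not guaranteed",
                    stacklevel=2,
                )

    def channels_of_class(self, cls: str) -> list[str]:
        return [name for name, k in self.channel_map if k == cls]

    def to_yaml(self, path) -> None:
        if any(r.mask is not None for r in self.regions) or (
            self.subclone is not None and self.subclone.mask is not None
        ):
            raise ValueError("only bbox-defined configs can be serialized to YAML")
        doc = {
            "image_shape": list(self.image_shape),
            "n_z": self.n_z,
            "channel_map": [list(t) for t in self.channel_map],
            "regions": [
                {
                    "region_id": r.region_id,
                    "bbox": list(r.bbox),
                    "tumor_content": r.tumor_content,
                    "density": r.density,
                    "mutant_fraction": r.mutant_fraction,
                }
                for r in self.regions
            ],
            "subclone": None
            if self.subclone is None
            else {
                "parent_region": self.subclone.parent_region,
                "bbox": list(self.subclone.bbox),
                "mutant_fraction": self.subclone.mutant_fraction,
            },
            "unspecific_rate": self.unspecific_rate,
            "psf_sigma": self.psf_sigma,
            "spot_amplitude": self.spot_amplitude,
            "background_level": self.background_level,
            "noise_model": [self.noise_model[0], self.noise_model[1]],
            "control_density": self.control_density,
            "nuclei_density": self.nuclei_density,
            "nuclei_sigma": self.nuclei_sigma,
            "content_field_amplitude": self.content_field_amplitude,
            "content_field_sigma": self.content_field_sigma,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        regions = [
            RegionSpec(
                region_id=int(r["region_id"]),
                bbox=tuple(r["bbox"]),
                tumor_content=float(r["tumor_content"]),
                density=float(r["density"]),
                mutant_fraction=float(r["mutant_fraction"]),
            )
            for r in doc.get("regions", [])
        ]
        sub = doc.get("subclone")
        subclone = (
            None
            if sub is None
            else SubcloneSpec(
                parent_region=int(sub["parent_region"]),
                bbox=tuple(sub["bbox"]),
                mutant_fraction=float(sub["mutant_fraction"]),
            )
        )
        nm = doc.get("noise_model", ["poisson", None])
        return cls(
            image_shape=tuple(doc["image_shape"]),
            n_z=int(doc.get("n_z", 3)),
            channel_map=[tuple(t) for t in doc["channel_map"]],
            regions=regions,
            subclone=subclone,
            unspecific_rate=float(doc.get("unspecific_rate", 0.015)),
            psf_sigma=float(doc.get("psf_sigma", 1.5)),
            spot_amplitude=float(doc.get("spot_amplitude", 200.0)),
            background_level=float(doc.get("background_level", 20.0)),
            noise_model=(nm[0], None if nm[1] is None else float(nm[1])),
            control_density=float(doc.get("control_density", 0.0)),
            nuclei_density=float(doc.get("nuclei_density", 1e-4)),
            nuclei_sigma=float(doc.get("nuclei_sigma", 6.0)),
            content_field_amplitude=float(doc.get("content_field_amplitude", 0.05)),
            content_field_sigma=float(doc.get("content_field_sigma", 64.0)),
            seed=int(doc.get("seed", 0)),
        )


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must rediscover.

    ``spots`` has one row per rendered spot: x, y (continuous, pixel units),
    z plane, region id, true class, and the channel(s) it was rendered into
    ("+"-joined for unspecific spots). ``labels`` and ``tumor_content`` are
    the region label mask and content map actually used, so a matching
    RegionLayout can be built without re-deriving geometry.
    """

    spots: pd.DataFrame
    region_summary: pd.DataFrame
    labels: np.ndarray
    tumor_content: np.ndarray
    control_region: int | None = None

    def true_mutant_fraction(self, region_id: int) -> float:
        sub = self.spots[self.spots["region"] == region_id]
        wt = int((sub["cls"] == "wildtype").sum())
        mu = int((sub["cls"] == "mutant").sum())
        if wt + mu == 0:
            return math.nan
        return mu / (wt + mu)

    def layout(self) -> RegionLayout:
        if self.control_region is None:
            raise ValueError("no control region designated in this simulation")
        return RegionLayout(
            labels=self.labels,
            tumor_content=self.tumor_content,
            control_region=self.control_region,
        )


def _add_blob(plane: np.ndarray, y: float, x: float, amplitude: float, sigma: float) -> None:
    nrows, ncols = plane.shape
    r = int(math.ceil(4 * sigma))
    r0, r1 = max(0, int(y) - r), min(nrows, int(y) + r + 1)
    c0, c1 = max(0, int(x) - r), min(ncols, int(x) + r + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy = np.arange(r0, r1, dtype=np.float64)[:, None]
    xx = np.arange(c0, c1, dtype=np.float64)[None, :]
    plane[r0:r1, c0:c1] += amplitude * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2)
    )


def _content_map(config: SimConfig, labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    content = np.zeros(config.image_shape, dtype=np.float64)
    for r in config.regions:
        content[labels == r.region_id] = r.tumor_content
    if config.content_field_amplitude > 0:
        noise = rng.standard_normal(config.image_shape)
        smooth = ndimage.gaussian_filter(noise, config.content_field_sigma)
        peak = np.abs(smooth).max()
        if peak > 0:
            smooth *= config.content_field_amplitude / peak
        content = np.where(labels > 0, np.clip(content + smooth, 0.0, 1.0), 0.0)
    return content


def simulate_tissue(
    config: SimConfig, control_region: int | None = None
) -> tuple[dict[str, ChannelStack], GroundTruth]:
    """Render one simulated acquisition.

    Returns one ChannelStack per channel-map entry plus the ground truth.
    Spot counts per region are Poisson(density × area); locations are
    uniform over the region mask; classes are drawn per spot (unspecific
    with probability ``unspecific_rate``, else mutant with the local mutant
    fraction — the sub-clonal patch overrides its parent's). Unspecific
    spots are rendered at identical coordinates and z in two distinct
    non-nuclear channels. The nuclear channel carries blob "nuclei"
    unrelated to any spot.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = config.image_shape
    labels = np.zeros(shape, dtype=np.int16)
    masks: dict[int, np.ndarray] = {}
    for r in config.regions:
        m = r.resolve_mask(shape)
        masks[r.region_id] = m
        labels[m] = r.region_id
    sub_mask = (
        config.subclone.resolve_mask(shape) if config.subclone is not None else None
    )
    content = _content_map(config, labels, rng)

    non_nuclear = [name for name, k in config.channel_map if k != "nuclear"]
    nuclear_channels = [name for name, k in config.channel_map if k == "nuclear"]
    wt_channels = config.channels_of_class("wildtype")
    mut_channels = config.channels_of_class("mutant")
    ctl_channels = config.channels_of_class("control")

    records: list[dict] = []
    for r in config.regions:
        m = masks[r.region_id]
        area = int(m.sum())
        flat_idx = np.flatnonzero(m)
        # informative (probe-bearing) spots
        n_spots = rng.poisson(r.density * area)
        if n_spots > 0:
            pix = rng.choice(flat_idx, size=n_spots, replace=True)
            ys = pix // shape[1] + rng.random(n_spots)
            xs = pix % shape[1] + rng.random(n_spots)
            zs = rng.integers(0, config.n_z, size=n_spots)
            u = rng.random(n_spots)
            is_unspec = u < config.unspecific_rate
            frac = np.full(n_spots, r.mutant_fraction)
            if sub_mask is not None and config.subclone.parent_region == r.region_id:
                inside = sub_mask[ys.astype(int), xs.astype(int)]
                frac[inside] = config.subclone.mutant_fraction
            is_mut = rng.random(n_spots) < frac
            for i in range(n_spots):
                if is_unspec[i]:
                    chans = list(rng.choice(non_nuclear, size=2, replace=False))
                    cls = "unspecific"
                elif is_mut[i]:
                    chans = [mut_channels[0]] if mut_channels else []
                    cls = "mutant"
                else:
                    chans = [wt_channels[0]] if wt_channels else []
                    cls = "wildtype"
                records.append(
                    {
                        "x": float(xs[i]), "y": float(ys[i]), "z": int(zs[i]),
                        "region": r.region_id, "cls": cls,
                        "channels": "+".join(chans),
                    }
                )
        # positive-control transcripts, if a control channel exists
        if ctl_channels and config.control_density > 0:
            n_ctl = rng.poisson(config.control_density * area)
            if n_ctl > 0:
                pix = rng.choice(flat_idx, size=n_ctl, replace=True)
                ys = pix // shape[1] + rng.random(n_ctl)
                xs = pix % shape[1] + rng.random(n_ctl)
                zs = rng.integers(0, config.n_z, size=n_ctl)
                for i in range(n_ctl):
                    records.append(
                        {
                            "x": float(xs[i]), "y": float(ys[i]), "z": int(zs[i]),
                            "region": r.region_id, "cls": "control",
                            "channels": ctl_channels[0],
                        }
                    )

    spots = pd.DataFrame(
        records, columns=["x", "y", "z", "region", "cls", "channels"]
    )

    # render channels
    channels: dict[str, ChannelStack] = {}
    cls_by_name = dict(config.channel_map)
    planes: dict[str, np.ndarray] = {
        name: np.full((config.n_z, *shape), config.background_level, dtype=np.float64)
        for name, _ in config.channel_map
    }
    for rec in records:
        for ch in rec["channels"].split("+"):
            if ch:
                _add_blob(
                    planes[ch][rec["z"]], rec["y"], rec["x"],
                    config.spot_amplitude, config.psf_sigma,
                )
    # nuclei: clusters in the nuclear channel, spanning all z planes
    if nuclear_channels and config.nuclei_density > 0:
        n_nuc = rng.poisson(config.nuclei_density * shape[0] * shape[1])
        ys = rng.random(n_nuc) * shape[0]
        xs = rng.random(n_nuc) * shape[1]
        for name in nuclear_channels:
            for y, x in zip(ys, xs):
                for z in range(config.n_z):
                    _add_blob(
                        planes[name][z], y, x,
                        config.spot_amplitude * 0.5, config.nuclei_sigma,
                    )

    model, param = config.noise_model
    for name, _cls in config.channel_map:
        clean = planes[name]
        if model == "poisson":
            noisy = rng.poisson(clean).astype(np.uint16)
        elif model == "gaussian":
            noisy = np.clip(clean + rng.normal(0.0, param, clean.shape), 0, None)
            noisy = noisy.astype(np.float32)
        else:
            raise ValueError(f"unknown noise model {model!r}")
        channels[name] = ChannelStack(name=name, channel_class=cls_by_name[name], data=noisy)

    summary_rows = []
    for r in config.regions:
        sub = spots[spots["region"] == r.region_id]
        wt = int((sub["cls"] == "wildtype").sum())
        mu = int((sub["cls"] == "mutant").sum())
        summary_rows.append(
            {
                "region": r.region_id,
                "n_wildtype": wt,
                "n_mutant": mu,
                "n_control": int((sub["cls"] == "control").sum()),
                "n_unspecific": int((sub["cls"] == "unspecific").sum()),
                "true_mutant_fraction": mu / (wt + mu) if wt + mu else math.nan,
                "expected_count": r.density * int(masks[r.region_id].sum()),
            }
        )
    truth = GroundTruth(
        spots=spots,
        region_summary=pd.DataFrame(summary_rows),
        labels=labels,
        tumor_content=content,
        control_region=control_region,
    )
    return channels, truth


# ---------------------------------------------------------------------------
# preset emulating the four-area tumor with a rising mutant fraction
# ---------------------------------------------------------------------------

#: region ids of the preset: areas 1-4 then non-neoplastic control
K386_AREAS = (1, 2, 3, 4)
K386_CONTROL = 5
#: sub-clonal patch inside area 2 (its own id for separate quantification)
K386_SUBAREA_BBOX = (512, 768, 256, 512)


def k386_like_preset(
    mutant_fractions: tuple[float, float, float, float] = (0.01, 0.01, 0.06, 0.14),
    subclone_fraction: float = 0.07,
    control_fraction: float = 0.015,
    spots_per_area: float = 300.0,
    seed: int = 0,
) -> SimConfig:
    """Four tumor areas with rising mutant fraction, a sub-clonal patch in
    area 2, and a non-neoplastic control region at the assay's false-positive
    background level.

    Areas are 512×1280 px strips stacked vertically (image 2560×1280), each
    tiling exactly ten 256×256 fields of view; density is set so each area
    carries ``spots_per_area`` informative spots in expectation. All strips
    get scalar content 0.9 (the control strip is non-neoplastic tissue, but
    the >0.8 field gate is applied uniformly so its fields qualify too); the
    content wobble field adds ±0.05.
    """
    strip_h, width = 512, 1280
    area_px = strip_h * width
    density = spots_per_area / area_px
    regions = [
        RegionSpec(
            region_id=rid,
            bbox=((rid - 1) * strip_h, 0, strip_h, width),
            tumor_content=0.9,
            density=density,
            mutant_fraction=frac,
        )
        for rid, frac in zip(K386_AREAS, mutant_fractions)
    ]
    regions.append(
        RegionSpec(
            region_id=K386_CONTROL,
            bbox=((K386_CONTROL - 1) * strip_h, 0, strip_h, width),
            tumor_content=0.9,
            density=density,
            mutant_fraction=control_fraction,
        )
    )
    return SimConfig(
        image_shape=(strip_h * 5, width),
        n_z=3,
        channel_map=[("DAPI", "nuclear"), ("Cy3", "wildtype"), ("FITC", "mutant")],
        regions=regions,
        subclone=SubcloneSpec(
            parent_region=2, bbox=K386_SUBAREA_BBOX, mutant_fraction=subclone_fraction
        ),
        unspecific_rate=0.015,
        psf_sigma=1.5,
        spot_amplitude=200.0,
        background_level=20.0,
        noise_model=("poisson", None),
        nuclei_density=5e-5,
        seed=seed,
    )


def write_simulation(outdir, channels: dict[str, ChannelStack], truth: GroundTruth) -> None:
    """Write channel TIFFs, ground-truth CSV, label mask and legend."""
    import tifffile
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, stack in channels.items():
        tifffile.imwrite(out / f"channel_{name}.tif", stack.data, photometric="minisblack")
    truth.spots.to_csv(out / "ground_truth.csv", index=False)
    tifffile.imwrite(out / "region_labels.tif", truth.labels.astype(np.uint16))
    legend_rows = []
    for rid in truth.region_summary["region"]:
        m = truth.labels == rid
        legend_rows.append(
            {
                "region": int(rid),
                "tumor_content": float(truth.tumor_content[m].mean()) if m.any() else 0.0,
                "is_control": bool(truth.control_region == rid),
            }
        )
    pd.DataFrame(legend_rows).to_csv(out / "region_legend.csv", index=False)
    truth.region_summary.to_csv(out / "region_summary.csv", index=False)
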