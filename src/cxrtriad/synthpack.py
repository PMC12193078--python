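"""Seeded generator of synthetic chest-radiograph-like datasets.

The generator emulates the statistical layout of public chest X-ray
collections: single-channel PNG images plus a metadata CSV whose
``Finding Labels`` column holds ``|``-joined label strings ("No Finding"
for the all-negative row). Images are not photorealistic; they carry the
structure the downstream pipeline assumes —

* a fixed elliptical lung-field background shared by every image,
* one class-specific structured opacity (blob / ring / streak) per
  positive label, with amplitude ``opacity_contrast``,
* label vectors drawn from a Gaussian-copula model realizing configured
  per-class prevalence and pairwise co-occurrence (or a categorical draw
  in single-label mode),
* additive Gaussian pixel noise and occasional high-frequency artifacts
  (salt speckle or a bright line).

Everything is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.stats import norm

from .image import GrayImage

logger = logging.getLogger(__name__)

NO_FINDING = "No Finding"

CSV_COLUMNS = ["Image Index", "Finding Labels", "Patient Age", "Patient Gender", "View Position"]

DEFAULT_CLASSES = ("Normal", "Fibrosis", "Pneumonia")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset."""

    n_images: int = 300
    image_side: int = 64
    class_names: tuple[str, ...] = DEFAULT_CLASSES
    multi_label: bool = False
    class_prevalence: tuple[float, ...] | None = None
    cooccurrence: np.ndarray | None = None
    opacity_contrast: float = 0.5
    noise_sd: float = 0.05
    artifact_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_names = tuple(self.class_names)
        c = len(self.class_names)
        if self.image_side < 16:
            raise ValueError("image_side must be >= 16")
        if self.opacity_contrast < 0 or self.noise_sd < 0:
            raise ValueError("opacity_contrast and noise_sd must be >= 0")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ValueError("artifact_rate must be a probability")
        if self.class_prevalence is None:
            # imbalanced by default: first class over-represented, tail rare
            w = np.array([2.0**-k for k in range(c)])
            if self.multi_label:
                self.class_prevalence = tuple(np.clip(0.4 * w, 0.02, 1.0))
            else:
                self.class_prevalence = tuple(w / w.sum())
        self.class_prevalence = tuple(float(p) for p in self.class_prevalence)
        if len(self.class_prevalence) != c:
            raise ValueError(
                f"class_prevalence has {len(self.class_prevalence)} entries for {c} classes"
            )
        if any(p < 0 or p > 1 for p in self.class_prevalence):
            raise ValueError("prevalences must lie in [0, 1]")
        if self.cooccurrence is None:
            self.cooccurrence = np.eye(c)
        self.cooccurrence = np.asarray(self.cooccurrence, dtype=np.float64)
        if self.cooccurrence.shape != (c, c):
            raise ValueError("cooccurrence must be C x C")
        if not np.allclose(self.cooccurrence, self.cooccurrence.T):
            raise ValueError("cooccurrence must be symmetric")
        if not np.allclose(np.diag(self.cooccurrence), 1.0):
            raise ValueError("cooccurrence must have unit diagonal")


@dataclass
class LabeledDataset:
    """Images + binary multi-label matrix + per-image metadata records."""

    images: list[GrayImage]
    labels: np.ndarray  # (N, C) in {0, 1}
    records: list[dict]
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.images) != self.labels.shape[0] or len(self.records) != self.labels.shape[0]:
            raise ValueError("images, labels and records must agree in length")
        if self.labels.ndim != 2 or self.labels.shape[1] != len(self.class_names):
            raise ValueError("labels must be (N, C) with C = len(class_names)")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.images)

    def label_string(self, i: int) -> str:
        active = [name for name, bit in zip(self.class_names, self.labels[i]) if bit]
        return "|".join(active) if active else NO_FINDING

    def primary_labels(self) -> np.ndarray:
        """First positive class per row (used for stratification); -1 if none."""
        out = np.full(len(self), -1, dtype=np.int64)
        rows, cols = np.nonzero(self.labels)
        for r, c in zip(rows[::-1], cols[::-1]):
            out[r] = c
        return out

    def pixel_matrix(self) -> np.ndarray:
        """Stack images into an (N, H*W) float matrix (requires equal shapes)."""
        return np.stack([im.values.ravel() for im in self.images])


def parse_finding_labels(label_str: str, class_names: tuple[str, ...]) -> np.ndarray:
    """Turn a ``|``-joined label string into a binary vector.

    ``"No Finding"`` maps to the all-zero row; any other unknown token is an
    error rather than a silent drop.
    """
    vec = np.zeros(len(class_names), dtype=np.int8)
    s = label_str.strip()
    if not s or s == NO_FINDING:
        return vec
    index = {name: j for j, name in enumerate(class_names)}
    for token in s.split("|"):
        token = token.strip()
        if token == NO_FINDING:
            continue
        if token not in index:
            raise ValueError(f"unknown label token {token!r}; known classes: {class_names}")
        vec[index[token]] = 1
    return vec


# ---------------------------------------------------------------------------
# image synthesis


def _lung_field_background(side: int) -> np.ndarray:
    """Fixed elliptical two-lobe "lung field" on a darker plate."""
    r = (np.arange(side) + 0.5) / side
    rr, cc = np.meshgrid(r, r, indexing="ij")
    bg = np.full((side, side), 0.15)
    for cx in (0.32, 0.68):
        inside = ((rr - 0.52) / 0.36) ** 2 + ((cc - cx) / 0.20) ** 2 <= 1.0
        bg[inside] += 0.30
    return bg


def _class_pattern(side: int, class_idx: int) -> np.ndarray:
    """Deterministic unit-amplitude pattern for one class.

    Shape family cycles blob / ring / streak with the class index; the
    location and geometry come from an rng keyed on the class index alone,
    so the pattern is reproducible and parameter-free.
    """
    h = np.random.default_rng([917301, class_idx])
    r = (np.arange(side) + 0.5) / side
    rr, cc = np.meshgrid(r, r, indexing="ij")
    # keep pattern centers inside the lung fields
    cy = h.uniform(0.30, 0.72)
    cx = h.choice([h.uniform(0.22, 0.42), h.uniform(0.58, 0.78)])
    kind = class_idx % 3
    if kind == 0:  # Gaussian blob
        s = h.uniform(0.06, 0.10)
        pat = np.exp(-(((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * s**2)))
    elif kind == 1:  # ring
        rad = h.uniform(0.10, 0.16)
        width = 0.035
        dist = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
        pat = np.exp(-(((dist - rad) / width) ** 2))
    else:  # linear streak
        theta = h.uniform(0, np.pi)
        n0, n1 = np.cos(theta), np.sin(theta)
        d = (rr - cy) * n0 + (cc - cx) * n1
        along = (rr - cy) * -n1 + (cc - cx) * n0
        pat = np.exp(-((d / 0.03) ** 2)) * (np.abs(along) < 0.22)
    return pat


def _inject_artifact(img: np.ndarray, rng: np.random.Generator) -> None:
    side = img.shape[0]
    if rng.random() < 0.5:  # salt speckle
        k = max(3, side * side // 200)
        idx = rng.integers(0, side, size=(k, 2))
        img[idx[:, 0], idx[:, 1]] = 1.0
    else:  # bright line
        pos = rng.integers(0, side)
        if rng.random() < 0.5:
            img[pos, :] = np.maximum(img[pos, :], 0.9)
        else:
            img[:, pos] = np.maximum(img[:, pos], 0.9)


def _copula_root(corr: np.ndarray) -> np.ndarray:
    """Matrix square root of the latent correlation (eigen-clipped if needed)."""
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def sample_labels(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the (N, C) binary label matrix for the configured label model."""
    n, c = config.n_images, len(config.class_names)
    prev = np.asarray(config.class_prevalence)
    if not config.multi_label:
        probs = prev / prev.sum()
        idx = rng.choice(c, size=n, p=probs)
        labels = np.zeros((n, c), dtype=np.int8)
        labels[np.arange(n), idx] = 1
        return labels
    # Gaussian copula: threshold correlated normals at the prevalence quantile
    root = _copula_root(config.cooccurrence)
    z = rng.standard_normal((n, c)) @ root.T
    with np.errstate(divide="ignore"):
        thresh = norm.ppf(prev)
    return (z < thresh).astype(np.int8)


def generate_dataset(config: SynthConfig) -> LabeledDataset:
    """Generate a dataset; bitwise deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    labels = sample_labels(config, rng)
    side = config.image_side
    bg = _lung_field_background(side)
    patterns = [_class_pattern(side, j) for j in range(len(config.class_names))]

    images: list[GrayImage] = []
    records: list[dict] = []
    for i in range(config.n_images):
        img = bg.copy()
        for j in np.nonzero(labels[i])[0]:
            img += config.opacity_contrast * patterns[j]
        if config.noise_sd > 0:
            img += rng.normal(0.0, config.noise_sd, size=img.shape)
        if rng.random() < config.artifact_rate:
            _inject_artifact(img, rng)
        np.clip(img, 0.0, 1.0, out=img)
        images.append(GrayImage(img, "unit"))
        records.append(
            {
                "Image Index": f"{i:08d}_000.png",
                "Finding Labels": "",  # filled below from the label row
                "Patient Age": int(rng.integers(18, 90)),
                "Patient Gender": str(rng.choice(["M", "F"])),
                "View Position": str(rng.choice(["PA", "AP"])),
            }
        )
    ds = LabeledDataset(images, labels, records, config.class_names)
    for i, rec in enumerate(ds.records):
        rec["Finding Labels"] = ds.label_string(i)
    return ds


# ---------------------------------------------------------------------------
# PNG + CSV round trip


def write_dataset(ds: LabeledDataset, directory: str | Path) -> dict:
    """Write one 8-bit grayscale PNG per image plus a metadata CSV.

    Intensities are quantized to 8 bits only at this boundary; in memory
    they stay real-valued in [0, 1].
    """
    directory = Path(directory)
    img_dir = directory / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for im, rec in zip(ds.images, ds.records):
        if im.value_range == "unit":
            q = np.round(np.clip(im.values, 0.0, 1.0) * 255.0)
        elif im.value_range == "raw-8bit":
            q = np.round(np.clip(im.values, 0.0, 255.0))
        else:
            raise ValueError("cannot write standardized images as 8-bit PNG")
        Image.fromarray(q.astype(np.uint8), mode="L").save(img_dir / rec["Image Index"])
    csv_path = directory / "Data_Entry.csv"
    pd.DataFrame(ds.records, columns=CSV_COLUMNS).to_csv(csv_path, index=False)
    return {
        "csv": str(csv_path),
        "image_dir": str(img_dir),
        "n_images": len(ds),
        "class_names": list(ds.class_names),
    }


def read_dataset(directory: str | Path, class_names: tuple[str, ...] | None = None) -> LabeledDataset:
    """Read a PNG+CSV dataset back; unreadable PNGs are skipped with a warning.

    When ``class_names`` is omitted the class list is the sorted union of
    tokens found in the ``Finding Labels`` column ("No Finding" excluded).
    """
    directory = Path(directory)
    df = pd.read_csv(directory / "Data_Entry.csv", dtype={"Finding Labels": str})
    if class_names is None:
        tokens: set[str] = set()
        for s in df["Finding Labels"].fillna(NO_FINDING):
            tokens.update(t.strip() for t in s.split("|"))
        tokens.discard(NO_FINDING)
        tokens.discard("")
        class_names = tuple(sorted(tokens))
    img_dir = directory / "images"
    images, rows, records = [], [], []
    for _, rec in df.iterrows():
        path = img_dir / rec["Image Index"]
        try:
            with Image.open(path) as fh:
                arr = np.asarray(fh.convert("L"), dtype=np.float64) / 255.0
        except (OSError, FileNotFoundError) as exc:
            logger.warning("skipping unreadable image %s (%s)", path, exc)
            warnings.warn(f"skipping unreadable image {path}", stacklevel=2)
            continue
        images.append(GrayImage(arr, "unit"))
        rows.append(parse_finding_labels(str(rec["Finding Labels"]), class_names))
        records.append(dict(rec))
    labels = np.stack(rows) if rows else np.zeros((0, len(class_names)), dtype=np.int8)
    return LabeledDataset(images, labels, records, class_names)
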