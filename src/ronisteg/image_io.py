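"""Reading, writing and min-max normalization of 12/16-bit medical images.

Covers are monochrome single-frame DICOM files (12 or 16 bit stored) or 16-bit
grayscale PNG. Every pipeline stage works on a [0, 1] normalized view of the
pixels; the affine map and its exact integer inverse live here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

from .errors import DegenerateRangeError, RangeError, UnsupportedFormatError

__all__ = [
    "Modality",
    "MedicalImage",
    "NormalizedImage",
    "read_image",
    "write_image",
    "normalize",
    "denormalize",
]


class Modality(enum.Enum):
    CT = "CT"
    MR = "MR"
    OTHER = "OTHER"


@dataclass
class MedicalImage:
    """Integer-valued 2D medical frame.

    ``pixels`` is a non-negative integer array with every value in
    ``[0, 2**bit_depth - 1]``; frames smaller than 8x8 are rejected because a
    cover must hold at least a couple of 4x4 transform tiles.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    modality: Modality = Modality.OTHER
    source_path: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.shape[0] < 8 or arr.shape[1] < 8:
            raise ValueError(f"pixels must be a 2D array of at least 8x8, got shape {arr.shape}")
        if self.bit_depth not in (12, 16):
            raise ValueError(f"bit_depth must be 12 or 16, got {self.bit_depth}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise RangeError("pixel values must be integers")
            arr = arr.astype(np.int64)
        if arr.size and (arr.min() < 0 or arr.max() > self.max_value):
            raise RangeError(
                f"pixel values must lie in [0, {self.max_value}] for bit depth {self.bit_depth}"
            )
        self.pixels = np.ascontiguousarray(arr.astype(np.uint16))

    @property
    def max_value(self) -> int:
        """Peak value R of the stored data type (2^bit_depth - 1)."""
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class NormalizedImage:
    """Real-valued [0, 1] view of a cover plus the affine map that made it."""

    values: np.ndarray
    norm_min: float
    norm_max: float

    def __post_init__(self) -> None:
        if self.norm_max <= self.norm_min:
            raise DegenerateRangeError("norm_max must exceed norm_min")
        self.values = np.clip(np.asarray(self.values, dtype=np.float64), 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def _read_dicom(path: Path) -> MedicalImage:
    import pydicom

    ds = pydicom.dcmread(str(path))
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise UnsupportedFormatError(f"{path}: color DICOM is not supported")
    if int(getattr(ds, "NumberOfFrames", 1)) != 1:
        raise UnsupportedFormatError(f"{path}: multi-frame DICOM is not supported")
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise UnsupportedFormatError(f"{path}: expected a single 2D frame, got shape {arr.shape}")
    bits_stored = int(getattr(ds, "BitsStored", 16))
    if bits_stored not in (12, 16):
        raise UnsupportedFormatError(f"{path}: BitsStored must be 12 or 16, got {bits_stored}")
    modality = {"CT": Modality.CT, "MR": Modality.MR}.get(
        str(getattr(ds, "Modality", "")), Modality.OTHER
    )
    return MedicalImage(arr, bit_depth=bits_stored, modality=modality, source_path=str(path))


def _read_png(path: Path) -> MedicalImage:
    img = PILImage.open(path)
    if img.mode in ("I;16", "I;16B", "I", "L"):
        arr = np.asarray(img, dtype=np.int64)
    else:
        raise UnsupportedFormatError(f"{path}: PNG mode {img.mode!r} is not grayscale")
    if arr.ndim != 2:
        raise UnsupportedFormatError(f"{path}: expected 2D grayscale PNG")
    return MedicalImage(arr, bit_depth=16, modality=Modality.OTHER, source_path=str(path))


def read_image(path: str | Path) -> MedicalImage:
    """Read a monochrome DICOM or grayscale PNG, pixels unmodified.

    Bit depth is taken from the DICOM BitsStored attribute; PNG covers are
    treated as 16-bit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom", ""):
        return _read_dicom(path)
    if suffix == ".png":
        return _read_png(path)
    # fall back on content sniffing: DICOM preamble magic at offset 128
    with open(path, "rb") as fh:
        head = fh.read(132)
    if head[128:132] == b"DICM":
        return _read_dicom(path)
    raise UnsupportedFormatError(f"{path}: unrecognized image format")


def _write_dicom(img: MedicalImage, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = img.modality.value if img.modality is not Modality.OTHER else "OT"
    ds.Rows, ds.Columns = img.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = img.bit_depth
    ds.HighBit = img.bit_depth - 1
    ds.PixelRepresentation = 0
    ds.PixelData = np.ascontiguousarray(img.pixels, dtype="<u2").tobytes()
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)


def write_image(img: MedicalImage, path: str | Path, format: str = "DICOM") -> None:
    """Write ``img`` so that :func:`read_image` round-trips pixel-identically.

    ``format`` is ``"DICOM"`` or ``"PNG"``; PNG output is a 16-bit grayscale
    file (a 12-bit image is stored unscaled in the 16-bit container).
    """
    path = Path(path)
    fmt = format.upper()
    if fmt == "DICOM":
        _write_dicom(img, path)
    elif fmt == "PNG":
        PILImage.fromarray(img.pixels.astype(np.uint16)).save(path)
    else:
        raise ValueError(f"format must be DICOM or PNG, got {format!r}")


def normalize(img: MedicalImage) -> NormalizedImage:
    """Min-max map of the pixels onto [0, 1].

    ``Norm(Img) = (Img - min(Img)) / (max(Img) - min(Img))``; the source
    extrema are recorded so :func:`denormalize` is an exact inverse.
    """
    lo = float(img.pixels.min())
    hi = float(img.pixels.max())
    if hi == lo:
        raise DegenerateRangeError("constant image cannot be min-max normalized")
    values = (img.pixels.astype(np.float64) - lo) / (hi - lo)
    return NormalizedImage(values=values, norm_min=lo, norm_max=hi)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (bit-reproducible across platforms)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def denormalize(
    nimg: NormalizedImage,
    bit_depth: int = 16,
    modality: Modality = Modality.OTHER,
) -> MedicalImage:
    """Inverse affine map back to integers, clamped to the bit-depth range.

    Uses the stored extrema, rounds half away from zero, then clamps to
    ``[0, 2**bit_depth - 1]`` (the clamp absorbs small post-IDCT under/
    overshoot). ``denormalize(normalize(img))`` reproduces ``img`` exactly.
    """
    peak = (1 << bit_depth) - 1
    raw = nimg.values * (nimg.norm_max - nimg.norm_min) + nimg.norm_min
    ints = np.clip(_round_half_away(raw), 0, peak).astype(np.uint16)
    return MedicalImage(ints, bit_depth=bit_depth, modality=modality)
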