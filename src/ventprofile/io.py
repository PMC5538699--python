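"""Plain-text interchange formats.

Contours are two-column ``x_mm,y_mm`` CSV files; a geometry bundle is a
directory of contour CSVs plus ``geometry.toml``; voltage recordings are
frame-per-row CSVs (``t_s`` then one column per channel, invalid channels
NaN) with a ``scheme.toml`` sidecar; images and masks are whitespace
matrices with row 0 anterior.  Reconstruction matrices are stored as ``.npz``
with a ``recon.toml`` metadata sidecar.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .forward import StimulationScheme
from .geometry import Contour, ThoraxGeometry
from .inverse import GnConfig, GreitConfig, ReconstructionMatrix
from .pipeline import VoltageSeries
from .profiles import VentilationProfile

__all__ = [
    "save_contour_csv",
    "load_contour_csv",
    "save_geometry_bundle",
    "load_geometry_bundle",
    "save_voltage_series",
    "load_voltage_series",
    "save_image_txt",
    "load_image_txt",
    "save_mask_txt",
    "load_mask_txt",
    "save_profile_csv",
    "load_profile_csv",
    "save_reconstruction_matrix",
    "load_reconstruction_matrix",
    "dump_toml",
]


def dump_toml(data: dict, path: Path) -> None:
    """Write a flat (one-level) TOML document."""
    lines = []
    for key, value in data.items():
        if isinstance(value, dict):
            lines.append(f"[{key}]")
            for k, v in value.items():
                lines.append(f"{k} = {_toml_value(v)}")
        else:
            lines.append(f"{key} = {_toml_value(value)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def load_toml(path: Path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


# -- contours and geometry bundles ------------------------------------------


def save_contour_csv(c: Contour, path: Path) -> None:
    df = pd.DataFrame(c.vertices, columns=["x_mm", "y_mm"])
    df.to_csv(path, index=False)


def load_contour_csv(path: Path, label: str = "") -> Contour:
    df = pd.read_csv(path)
    return Contour(df[["x_mm", "y_mm"]].to_numpy(dtype=float), label=label or Path(path).stem)


_ORGAN_FILES = {"lung_right": "lung_right.csv", "lung_left": "lung_left.csv", "heart": "heart.csv"}


def save_geometry_bundle(g: ThoraxGeometry, directory: Path, n_electrodes: int = 32) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_contour_csv(g.thorax, d / "thorax.csv")
    for lung in g.lungs:
        name = lung.label if lung.label in ("lung_right", "lung_left") else None
        if name is None:
            name = "lung_right" if lung.centroid[0] < 0 else "lung_left"
        save_contour_csv(lung, d / f"{name}.csv")
    if g.heart is not None:
        save_contour_csv(g.heart, d / "heart.csv")
    dump_toml(
        {
            "kind": g.kind,
            "n_electrodes": n_electrodes,
            "belt_orientation": "clockwise-from-cranial",
        },
        d / "geometry.toml",
    )


def load_geometry_bundle(directory: Path) -> ThoraxGeometry:
    d = Path(directory)
    meta = load_toml(d / "geometry.toml")
    thorax = load_contour_csv(d / "thorax.csv", "thorax")
    lungs = []
    for name in ("lung_right", "lung_left"):
        p = d / f"{name}.csv"
        if p.exists():
            lungs.append(load_contour_csv(p, name))
    heart = None
    if (d / "heart.csv").exists():
        heart = load_contour_csv(d / "heart.csv", "heart")
    return ThoraxGeometry(
        thorax=thorax, lungs=tuple(lungs), heart=heart, kind=meta.get("kind", "individual")
    )


# -- voltage series ----------------------------------------------------------


def save_voltage_series(s: VoltageSeries, directory: Path, extra_meta: dict | None = None) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cols = [f"ch_{i:04d}" for i in range(s.values.shape[1])]
    df = pd.DataFrame(s.values, columns=cols)
    df.insert(0, "t_s", s.timestamps)
    df.to_csv(d / "voltages.csv", index=False, float_format="%.10g")
    meta = {
        "n_electrodes": s.scheme.n_electrodes,
        "skip": s.scheme.skip,
        "amplitude_mA": s.scheme.amplitude_mA,
        "sampling_rate_hz": s.sampling_rate,
    }
    meta.update(extra_meta or {})
    dump_toml(meta, d / "scheme.toml")


def load_voltage_series(directory: Path) -> tuple[VoltageSeries, dict]:
    d = Path(directory)
    meta = load_toml(d / "scheme.toml")
    df = pd.read_csv(d / "voltages.csv")
    scheme = StimulationScheme(
        n_electrodes=int(meta["n_electrodes"]),
        skip=int(meta["skip"]),
        amplitude_mA=float(meta["amplitude_mA"]),
    )
    series = VoltageSeries(
        values=df.drop(columns="t_s").to_numpy(dtype=float),
        timestamps=df["t_s"].to_numpy(dtype=float),
        scheme=scheme,
        sampling_rate=float(meta["sampling_rate_hz"]),
    )
    return series, meta


# -- images, masks, profiles -------------------------------------------------


def save_image_txt(img: np.ndarray, path: Path) -> None:
    np.savetxt(path, np.asarray(img, dtype=float), fmt="%.8g")


def load_image_txt(path: Path) -> np.ndarray:
    return np.loadtxt(path, dtype=float)


def save_mask_txt(mask: np.ndarray, path: Path) -> None:
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d")


def load_mask_txt(path: Path) -> np.ndarray:
    return np.loadtxt(path, dtype=int).astype(bool)


def save_profile_csv(p: VentilationProfile, path: Path) -> None:
    pd.DataFrame(
        {"band_index": np.arange(p.n_regions), "vd_percent": p.values}
    ).to_csv(path, index=False, float_format="%.8g")


def load_profile_csv(path: Path) -> VentilationProfile:
    df = pd.read_csv(path)
    v = df["vd_percent"].to_numpy(dtype=float)
    total = v.sum()
    if abs(total - 100.0) > 1e-3:
        raise ValueError(f"profile in {path} sums to {total}, not 100%")
    return VentilationProfile(v * (100.0 / total))  # undo text rounding


# -- reconstruction matrices -------------------------------------------------


def save_reconstruction_matrix(R: ReconstructionMatrix, directory: Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(d / "recon.npz", matrix=R.matrix, body_mask=R.body_mask)
    meta = {
        "algorithm": R.algorithm,
        "lam": R.lam if R.lam is not None else float("nan"),
        "achieved_nf": R.achieved_nf if R.achieved_nf is not None else float("nan"),
        "mesh_fingerprint": R.mesh_fingerprint,
        "geometry_kind": R.geometry_kind,
        "n_electrodes": R.n_electrodes,
        "skip": R.skip,
    }
    if R.config is not None:
        cfg = {"nf": R.config.nf, "background": R.config.background, "reference": R.config.reference}
        if isinstance(R.config, GreitConfig):
            cfg.update(ts=R.config.ts, rw=R.config.rw)
        else:
            cfg.update(prior=R.config.prior)
        meta["config"] = cfg
    dump_toml(meta, d / "recon.toml")


def load_reconstruction_matrix(directory: Path) -> ReconstructionMatrix:
    d = Path(directory)
    meta = load_toml(d / "recon.toml")
    arrays = np.load(d / "recon.npz")
    cfg = None
    if "config" in meta:
        c = meta["config"]
        if meta["algorithm"] == "greit":
            cfg = GreitConfig(
                nf=c["nf"], ts=c["ts"], rw=c["rw"],
                background=c["background"], reference=c["reference"],
            )
        else:
            cfg = GnConfig(
                nf=c["nf"], prior=c["prior"],
                background=c["background"], reference=c["reference"],
            )
    return ReconstructionMatrix(
        matrix=arrays["matrix"],
        body_mask=arrays["body_mask"].astype(bool),
        algorithm=meta["algorithm"],
        config=cfg,
        lam=meta.get("lam"),
        achieved_nf=meta.get("achieved_nf"),
        mesh_fingerprint=meta.get("mesh_fingerprint", ""),
        geometry_kind=meta.get("geometry_kind", ""),
        n_electrodes=int(meta.get("n_electrodes", 32)),
        skip=int(meta.get("skip", 4)),
    )
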