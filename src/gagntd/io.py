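"""Plain-text I/O for scan sets, equilibrium profiles, ITC schedules and C(S).

Velocity scan sets are written one columnar text file per scan (a header of
``key: value`` lines followed by two columns: radius_cm, signal) plus a JSON
manifest recording rotor speed, channel, geometry and the scan file list --
a simple dialect modelled on XL-I instrument output.  Equilibrium profiles
and ITC schedules are CSV; C(S) distributions are a two-column CSV with a
JSON sidecar for f/f0, regularisation and rmsd.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .lamm import CellGeometry
from .simulate import ITCTitration, SEProfile, SEProfileSet, SVScanSet
from .svfit import CSDistribution


def write_sv_scans(scans: SVScanSet, directory) -> Path:
    """Write one text file per scan plus ``manifest.json``; returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, t in enumerate(scans.scan_times):
        name = f"scan_{i:04d}.txt"
        with open(directory / name, "w") as fh:
            fh.write(f"# rotor_speed_rad_s: {scans.omega!r}\n")
            fh.write(f"# time_s: {float(t)!r}\n")
            fh.write(f"# channel: {scans.channel}\n")
            fh.write("# columns: radius_cm signal\n")
            for r, a in zip(scans.radii, scans.signals[i]):
                fh.write(f"{r:.6f} {a:.6e}\n")
        files.append(name)
    g = scans.geometry
    manifest = {
        "omega_rad_s": scans.omega,
        "channel": scans.channel,
        "noise_sigma": scans.noise_sigma,
        "geometry": {"meniscus": g.meniscus, "base": g.base,
                     "pathlength": g.pathlength,
                     "sector_angle": g.sector_angle},
        "scans": files,
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_sv_scans(manifest_path) -> SVScanSet:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    g = manifest["geometry"]
    geometry = CellGeometry(meniscus=g["meniscus"], base=g["base"],
                            pathlength=g["pathlength"],
                            sector_angle=g["sector_angle"])
    times, rows, radii = [], [], None
    for name in manifest["scans"]:
        data = np.loadtxt(manifest_path.parent / name)
        with open(manifest_path.parent / name) as fh:
            t = None
            for line in fh:
                if line.startswith("# time_s:"):
                    t = float(line.split(":", 1)[1])
                    break
        times.append(t)
        if radii is None:
            radii = data[:, 0]
        rows.append(data[:, 1])
    return SVScanSet(
        omega=manifest["omega_rad_s"], scan_times=np.array(times),
        radii=radii, signals=np.vstack(rows), channel=manifest["channel"],
        geometry=geometry, noise_sigma=manifest.get("noise_sigma", 0.0),
    )


def write_se_profiles(profiles: SEProfileSet, path) -> Path:
    frames = []
    for i, p in enumerate(profiles.profiles):
        frames.append(pd.DataFrame({
            "profile": i, "omega_rad_s": p.omega, "loading_mol_l": p.loading,
            "radius_cm": p.radii, "signal": p.signal,
        }))
    df = pd.concat(frames, ignore_index=True)
    df.attrs = {}
    path = Path(path)
    header = (f"# meniscus: {profiles.geometry.meniscus} "
              f"base: {profiles.geometry.base} "
              f"pathlength: {profiles.geometry.pathlength} "
              f"reference_radius: {profiles.reference_radius}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    return path


def read_se_profiles(path) -> SEProfileSet:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    tokens = header.lstrip("# ").split()
    meta = {tokens[i].rstrip(":"): float(tokens[i + 1])
            for i in range(0, len(tokens), 2)}
    geometry = CellGeometry(meniscus=meta["meniscus"], base=meta["base"],
                            pathlength=meta["pathlength"])
    profiles = []
    for _, grp in df.groupby("profile"):
        profiles.append(SEProfile(
            omega=float(grp["omega_rad_s"].iloc[0]),
            loading=float(grp["loading_mol_l"].iloc[0]),
            radii=grp["radius_cm"].to_numpy(),
            signal=grp["signal"].to_numpy(),
        ))
    return SEProfileSet(profiles=profiles, geometry=geometry,
                        reference_radius=meta["reference_radius"])


def write_itc(titration: ITCTitration, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "injection_volume_ml": titration.injection_volumes,
        "heat_ucal": titration.heats,
    })
    with open(path, "w") as fh:
        fh.write(f"# cell_volume_ml: {titration.cell_volume} "
                 f"cell_concentration_mol_l: {titration.cell_concentration} "
                 f"syringe_concentration_mol_l: {titration.syringe_concentration}\n")
        df.to_csv(fh, index=False)
    return path


def read_itc(path) -> ITCTitration:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    tokens = header.lstrip("# ").split()
    meta = {tokens[i].rstrip(":"): float(tokens[i + 1])
            for i in range(0, len(tokens), 2)}
    return ITCTitration(
        cell_volume=meta["cell_volume_ml"],
        cell_concentration=meta["cell_concentration_mol_l"],
        syringe_concentration=meta["syringe_concentration_mol_l"],
        injection_volumes=df["injection_volume_ml"].to_numpy(),
        heats=df["heat_ucal"].to_numpy(),
    )


def write_cs(csd: CSDistribution, path) -> Path:
    """Two-column CSV (s_svedberg, c_of_s) plus a ``.json`` sidecar."""
    path = Path(path)
    pd.DataFrame({"s_svedberg": csd.s_grid, "c_of_s": csd.amplitudes}).to_csv(
        path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "ff0": csd.ff0, "regularization": csd.regularization,
        "fit_rmsd": csd.fit_rmsd,
    }, indent=1))
    return path


def read_cs(path) -> CSDistribution:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return CSDistribution(
        s_grid=df["s_svedberg"].to_numpy(), amplitudes=df["c_of_s"].to_numpy(),
        ff0=meta.get("ff0", float("nan")),
        regularization=meta.get("regularization", 0.0),
        fit_rmsd=meta.get("fit_rmsd"),
    )
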