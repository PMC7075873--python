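"""Seeded generators for every input the analysis pipeline consumes.

Each generator returns its data together with a ground-truth dict (and the
save helpers write the truth as a JSON sidecar next to the data file), so
downstream recovery tests read truth only from the generator, never from the
pipeline under test.  All generators are bit-reproducible from their seed.

What is emulated, and what is not: angle series mimic the approach to
equilibrium and the stationary Gaussian fluctuations of trajectory
observables (not the underlying atomistic dynamics); rigid subunit pairs
carry exactly planted bend/twist rotations; membrane clouds are jittered
cylinder lattices; surface images are PSF-blurred elliptical bands with
shot/read noise standing in for structured-illumination data.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from mrebtwist.core_model import (
    FilamentParams,
    MONOMER_RISE_NM,
    energy_length_curve,
    limit_length,
    predicted_pitch,
)
from mrebtwist.patch_quantification import DEFAULT_PIXEL_SIZE_UM, SurfaceImage
from mrebtwist.trajectory_geometry import (
    AngleSeries,
    StructureFrame,
    SubunitTriad,
    compose_bend_twist,
)

#: printed equilibrium twist states (mean, SD) in degrees per monomer step
TWIST_STATES_DEG = {"ATP": (10.3, 2.1), "ADP": (4.2, 2.0)}


def gen_angle_series(mean_deg: float, sd_deg: float, n_frames: int = 200,
                     frame_dt_ns: float = 0.2, autocorr_time_ns: float = 2.0,
                     burn_in_ns: float = 60.0, seed: int = 0,
                     name: str = "theta3") -> tuple[AngleSeries, dict]:
    """Mean-reverting angle series relaxing from 0 to a stationary Gaussian.

    A discrete Ornstein-Uhlenbeck process with correlation time
    ``autocorr_time_ns`` tracks a target that relaxes from 0 to ``mean_deg``
    over ``burn_in_ns``; the stationary tail of ``n_frames`` frames is
    N(mean, sd).  Defaults mirror the published sampling (0.2 ns frames,
    200-frame / 40 ns equilibrium windows).
    """
    rng = np.random.default_rng(seed)
    n_burn = int(round(burn_in_ns / frame_dt_ns))
    n_tot = n_burn + n_frames
    times = np.arange(n_tot) * frame_dt_ns
    # target mean reaches ~99% of its plateau at the end of the burn-in
    relax = mean_deg * (1.0 - np.exp(-5.0 * times / burn_in_ns)) if burn_in_ns > 0 \
        else np.full(n_tot, mean_deg)
    rho = math.exp(-frame_dt_ns / autocorr_time_ns)
    x = np.empty(n_tot)
    x[0] = 0.0
    innov = rng.standard_normal(n_tot) * sd_deg * math.sqrt(1.0 - rho * rho)
    for i in range(1, n_tot):
        x[i] = relax[i] + rho * (x[i - 1] - relax[i - 1]) + innov[i]
    truth = {"mean_deg": mean_deg, "sd_deg": sd_deg, "n_frames": n_frames,
             "frame_dt_ns": frame_dt_ns, "autocorr_time_ns": autocorr_time_ns,
             "burn_in_ns": burn_in_ns, "seed": seed, "name": name}
    return AngleSeries(name, times, x), truth


def _template_subunit(rng: np.random.Generator, n_per_subdomain: int) -> tuple:
    """Asymmetric four-subdomain pseudo-atom cloud (coords nm, labels)."""
    offsets = {"IA": np.array([1.5, 0.0, -1.2]), "IB": np.array([1.2, 0.4, 1.4]),
               "IIA": np.array([-1.4, -0.3, -1.3]), "IIB": np.array([-1.3, 0.5, 1.3])}
    coords, labels = [], []
    for name, off in offsets.items():
        coords.append(off + rng.normal(scale=0.6, size=(n_per_subdomain, 3)))
        labels += [name] * n_per_subdomain
    return np.vstack(coords), np.array(labels, dtype=object)


def gen_rigid_pair(theta1_deg: float, theta2_deg: float, theta3_deg: float,
                   noise_nm: float = 0.0, seed: int = 0,
                   n_per_subdomain: int = 8, rise_nm: float = MONOMER_RISE_NM,
                   ) -> tuple[StructureFrame, StructureFrame, SubunitTriad, dict]:
    """Two-subunit frame with a planted inter-subunit bend/twist rotation.

    Returns (frame, reference_frame, reference_triad, truth).  The lab frame
    is chosen so the filament axis d3 is +z and the membrane normal is +y;
    the plus subunit is the minus template rotated by the planted angles
    (composed about d3, then d2, then d1) about the minus centroid, shifted
    by one rise along d3, with optional Gaussian positional noise.
    """
    rng = np.random.default_rng(seed)
    template, labels = _template_subunit(rng, n_per_subdomain)
    d3 = np.array([0.0, 0.0, 1.0])
    d2 = np.array([0.0, 1.0, 0.0])
    triad = SubunitTriad(origin=np.zeros(3), d1=np.cross(d3, d2), d2=d2, d3=d3)
    R = compose_bend_twist(triad, theta1_deg, theta2_deg, theta3_deg)
    minus = template - template.mean(axis=0)
    plus_ref = minus + rise_nm * d3
    plus = (R @ minus.T).T + rise_nm * d3

    def build(minus_c, plus_c, noise):
        coords = np.vstack([minus_c, plus_c])
        if noise > 0:
            coords = coords + rng.normal(scale=noise, size=coords.shape)
        n = len(template)
        return StructureFrame(
            coords=coords,
            radii=np.full(2 * n, 0.17),
            subunit=np.array(["minus"] * n + ["plus"] * n, dtype=object),
            subdomain=np.concatenate([labels, labels]),
            residue_index=np.concatenate([np.arange(n) + 9, np.arange(n) + 9]),
        )

    reference = build(minus, plus_ref, 0.0)
    frame = build(minus, plus, noise_nm)
    truth = {"theta1_deg": theta1_deg, "theta2_deg": theta2_deg,
             "theta3_deg": theta3_deg, "noise_nm": noise_nm, "seed": seed,
             "rise_nm": rise_nm}
    return frame, reference, triad, truth


def gen_membrane_cloud(curvature: float, extent_nm: float = 40.0,
                       spacing_nm: float = 1.0, noise_nm: float = 0.0,
                       seed: int = 0) -> tuple[np.ndarray, dict]:
    """Phosphate-like lattice on a cylinder of radius 1/curvature (nm^-1).

    Zero curvature gives a flat z = 0 sheet.  The cylinder axis runs along x
    and the sheet bulges towards +z (the protein side); positions are
    jittered by isotropic Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    half = extent_nm / 2.0
    xs = np.arange(-half, half + 1e-9, spacing_nm)
    ys = np.arange(-half, half + 1e-9, spacing_nm)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    if curvature == 0.0:
        Z = np.zeros_like(X)
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    else:
        r = 1.0 / curvature
        phi = Y / r     # Y is arc length around the cylinder
        pts = np.column_stack([X.ravel(), (r * np.sin(phi)).ravel(),
                               (r - r * np.cos(phi)).ravel()])
    if noise_nm > 0:
        pts = pts + rng.normal(scale=noise_nm, size=pts.shape)
    truth = {"curvature_per_nm": curvature, "extent_nm": extent_nm,
             "spacing_nm": spacing_nm, "noise_nm": noise_nm, "seed": seed,
             "protein_side": [0.0, 0.0, 1.0]}
    return pts, truth


def gen_surface_image(filaments, image_shape=(512, 512),
                      pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                      psf_sigma_um: float = 0.03, noise_level: float = 0.01,
                      background: float = 0.02, photons: float = 2000.0,
                      width_um: float = 0.15, seed: int = 0,
                      cell_id: str = "cell0") -> tuple[SurfaceImage, dict]:
    """Render filament bands on a flattened surface with PSF blur and noise.

    ``filaments`` is a sequence of dicts with keys ``length_um``,
    ``pitch_deg``, ``intensity`` and optionally ``center`` (row, col in
    pixels; placed on a collision-free jittered grid when absent).  Bands are
    solid ellipses (half-max thresholding of the blurred band then recovers
    the planted axis lengths); blur is an isotropic Gaussian PSF; noise is
    Poisson shot noise at ``photons`` counts per unit intensity plus Gaussian
    read noise of scale ``noise_level``.
    """
    rng = np.random.default_rng(seed)
    img = np.full(image_shape, background, dtype=float)
    ps = pixel_size_um
    placed = []
    # jittered-grid placement for filaments without explicit centres
    max_len_px = max([f["length_um"] / ps for f in filaments], default=10.0)
    cell_px = int(max_len_px + width_um / ps + 8)
    grid_rows = max(1, image_shape[0] // cell_px)
    grid_cols = max(1, image_shape[1] // cell_px)
    slots = [(i, j) for i in range(grid_rows) for j in range(grid_cols)]
    rng.shuffle(slots)
    slot_iter = iter(slots)
    for f in filaments:
        a = 0.5 * f["length_um"] / ps          # semi-major, px
        b = 0.5 * width_um / ps                # semi-minor, px
        if "center" in f:
            cr, cc = f["center"]
        else:
            try:
                i, j = next(slot_iter)
            except StopIteration:
                break   # image full; truth records only placed filaments
            jit = cell_px / 2 + rng.uniform(-2, 2, size=2)
            cr = i * cell_px + jit[0]
            cc = j * cell_px + jit[1]
        # pitch is measured from the long cell axis (image rows)
        ang = math.radians(f["pitch_deg"]) * (1 if rng.random() < 0.5 else -1)
        ux = math.cos(ang)   # along rows
        uy = math.sin(ang)   # along cols
        r0, r1 = int(max(0, cr - a - b - 2)), int(min(image_shape[0], cr + a + b + 3))
        c0, c1 = int(max(0, cc - a - b - 2)), int(min(image_shape[1], cc + a + b + 3))
        if r1 <= r0 or c1 <= c0:
            continue
        # 3x supersampled solid-ellipse indicator
        ss = 3
        rr = (np.arange(r0 * ss, r1 * ss) + 0.5) / ss - cr
        cc_ = (np.arange(c0 * ss, c1 * ss) + 0.5) / ss - cc
        RR, CC = np.meshgrid(rr, cc_, indexing="ij")
        u = RR * ux + CC * uy
        v = -RR * uy + CC * ux
        inside = ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(float)
        block = inside.reshape(r1 - r0, ss, c1 - c0, ss).mean(axis=(1, 3))
        img[r0:r1, c0:c1] += f["intensity"] * block
        placed.append({"length_um": f["length_um"], "pitch_deg": f["pitch_deg"],
                       "intensity": f["intensity"], "center": [float(cr), float(cc)]})
    img = gaussian_filter(img, sigma=psf_sigma_um / ps)
    img = rng.poisson(np.clip(img, 0, None) * photons) / photons
    img = img + rng.normal(scale=noise_level, size=img.shape)
    img = np.clip(img, 0.0, None)
    truth = {"filaments": placed, "pixel_size_um": ps, "psf_sigma_um": psf_sigma_um,
             "width_um": width_um, "noise_level": noise_level, "seed": seed}
    return SurfaceImage(img, pixel_size=ps, cell_id=cell_id), truth


def gen_mutant_panel(twist_means_deg=(3.0, 5.0, 8.0, 10.3, 12.0),
                     base_params: FilamentParams | None = None,
                     seed: int = 0, n_patches: int = 150,
                     cylinder_radius_nm: float = 400.0,
                     length_cap_nm: float = 800.0,
                     resolution_offset_um: float = 0.2,
                     length_spread: float = 0.35,
                     pitch_sd_deg: float = 3.0,
                     pitch_ref_length_nm: float = 200.0,
                     patches_per_image: int = 12,
                     image_shape=(512, 512)) -> dict:
    """End-to-end mutant panel: model predictions -> synthetic images.

    For each planted intrinsic twist (degrees per monomer step) the flat
    analytical model predicts the limit length (capped at ``length_cap_nm``
    where growth is energetically unbounded, standing in for the cell-size
    cap seen in vivo) and the quasi-1D cylinder model predicts the pitch
    angle.  Per-strain patch lengths are drawn log-normally with their 99th
    percentile at the predicted limit plus a constant resolution offset (the
    apparent size floor of diffraction-limited imaging); pitches are Gaussian
    around the prediction.  Images are rendered per strain and the full truth
    is carried in the returned dict.
    """
    base = base_params or FilamentParams.wild_type()
    rng = np.random.default_rng(seed)
    strains = []
    for s_idx, twist in enumerate(twist_means_deg):
        omega0 = math.radians(twist) / MONOMER_RISE_NM
        p = base.with_(omega0=omega0, r=math.inf)
        if omega0 > 0:
            prof = energy_length_curve(p, L_max=2.0 * length_cap_nm)
            lstar = limit_length(prof, p.mu0)
        else:
            lstar = math.inf
        l_eff_nm = min(lstar, length_cap_nm)
        # pitch evaluated at a fixed reference length so strains differ only
        # through their intrinsic twist, not through the length cap
        pitch_pred = predicted_pitch(pitch_ref_length_nm,
                                     p.with_(r=cylinder_radius_nm))
        # planted observed-length distribution: resolution offset + log-normal
        # tail whose 99th percentile sits at the predicted limit
        target_um = l_eff_nm / 1000.0
        mu_log = math.log(target_um) - 2.3263 * length_spread
        lengths = resolution_offset_um + np.exp(
            rng.normal(mu_log, length_spread, size=n_patches))
        pitch_center = 90.0 - abs(pitch_pred - 90.0)
        pitches = np.clip(rng.normal(pitch_center, pitch_sd_deg, size=n_patches),
                          0.0, 90.0)
        intensities = rng.uniform(0.8, 1.0, size=n_patches)
        images = []
        for img_idx in range(0, n_patches, patches_per_image):
            fil = [{"length_um": float(lengths[k]), "pitch_deg": float(pitches[k]),
                    "intensity": float(intensities[k])}
                   for k in range(img_idx, min(img_idx + patches_per_image, n_patches))]
            img, img_truth = gen_surface_image(
                fil, image_shape=image_shape,
                seed=int(rng.integers(2**31 - 1)),
                cell_id=f"strain{s_idx}_img{img_idx // patches_per_image}")
            images.append((img, img_truth))
        strains.append({
            "twist_deg": float(twist),
            "omega0_rad_per_nm": omega0,
            "limit_length_nm": float(lstar) if math.isfinite(lstar) else "unbounded",
            "planted_p99_um": float(resolution_offset_um + target_um * 1.0),
            "pitch_pred_deg": float(pitch_pred),
            "planted_pitch_mean_deg": float(pitch_center),
            "planted_lengths_um": lengths.tolist(),
            "planted_pitches_deg": pitches.tolist(),
            "images": images,
        })
    if len(strains) < 2:
        strains[0]["degenerate_correlation"] = True
    return {"seed": seed, "strains": strains,
            "cylinder_radius_nm": cylinder_radius_nm,
            "length_cap_nm": length_cap_nm}


# ---------------------------------------------------------------------------
# sidecar-writing helpers
# ---------------------------------------------------------------------------


def write_truth_sidecar(data_path, truth: dict) -> Path:
    """Write the ground-truth JSON next to a data file (.truth.json)."""
    p = Path(str(data_path) + ".truth.json")
    p.write_text(json.dumps(truth, indent=1, default=str))
    return p
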