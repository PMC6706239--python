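"""Pipeline orchestration and file I/O.

Results are written to a self-describing HDF5 container (groups ``/fid``,
``/spectra``, ``/csi``, ``/traces``, ``/maps``; every group carries the
config hash and seed as attributes), kinetic tables to CSV and fit reports
to JSON.  Identical config + seed produce byte-identical CSV/JSON outputs.

Vendor raw formats are not parsed natively; externally converted data enter
through the same HDF5 container layout written here.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import denoise, imaging, kinetics, preprocess, synthetic
from .config import RunConfig
from .datatypes import (
    AcquisitionParams,
    CSIDataset,
    FIDSeries,
    KineticTrace,
    PeakWindow,
    SpectrumSeries,
)

__all__ = [
    "run_pipeline",
    "preprocess_series",
    "write_container",
    "read_fid",
    "read_csi",
    "write_trace_csv",
    "read_trace_csv",
]

log = logging.getLogger("dynamrs")


# ----------------------------------------------------------------------------
# container I/O
# ----------------------------------------------------------------------------

def _write_params(grp: h5py.Group, params: AcquisitionParams) -> None:
    for k, v in vars(params).items():
        grp.attrs[k] = v


def _read_params(grp: h5py.Group) -> AcquisitionParams:
    fields = AcquisitionParams.__dataclass_fields__
    kwargs = {k: grp.attrs[k] for k in fields if k in grp.attrs}
    for k in ("n_points", "n_averages", "dead_time_points"):
        if k in kwargs:
            kwargs[k] = int(kwargs[k])
    return AcquisitionParams(**kwargs)


def write_container(path, *, fid: FIDSeries | None = None,
                    spectra: SpectrumSeries | None = None,
                    csi: CSIDataset | None = None,
                    maps: dict[str, np.ndarray] | None = None,
                    config_hash: str = "", seed: int = 0, mode: str = "w") -> None:
    with h5py.File(path, mode) as fh:
        fh.attrs["config_hash"] = config_hash
        fh.attrs["seed"] = seed
        if fid is not None:
            g = fh.require_group("fid")
            g.create_dataset("data", data=fid.data)
            g.create_dataset("frame_times", data=fid.frame_times)
            g.attrs["provenance"] = json.dumps(fid.provenance)
            _write_params(g, fid.params)
        if spectra is not None:
            g = fh.require_group("spectra")
            g.create_dataset("data", data=np.asarray(spectra.data, dtype=complex))
            g.create_dataset("ppm", data=spectra.ppm)
            g.create_dataset("frame_times", data=spectra.frame_times)
            g.attrs.update(
                reference_ppm=spectra.reference_ppm, phase0=spectra.phase0,
                phase1=spectra.phase1, mode=spectra.mode,
                provenance=json.dumps(spectra.provenance),
            )
        if csi is not None:
            g = fh.require_group("csi")
            g.create_dataset("data", data=csi.data)
            g.create_dataset("frame_times", data=csi.frame_times)
            g.attrs.update(
                fov=csi.fov, slab_thickness=csi.slab_thickness, domain=csi.domain,
                spectral_domain=csi.spectral_domain, provenance=json.dumps(csi.provenance),
            )
            _write_params(g, csi.params)
        if maps:
            g = fh.require_group("maps")
            for name, arr in maps.items():
                g.create_dataset(name, data=arr)


def read_fid(path) -> FIDSeries:
    with h5py.File(path, "r") as fh:
        g = fh["fid"]
        return FIDSeries(
            data=g["data"][()],
            frame_times=g["frame_times"][()],
            params=_read_params(g),
            provenance=tuple(json.loads(g.attrs.get("provenance", "[]"))),
        )


def read_csi(path) -> CSIDataset:
    with h5py.File(path, "r") as fh:
        g = fh["csi"]
        return CSIDataset(
            data=g["data"][()],
            fov=tuple(g.attrs["fov"]),
            slab_thickness=float(g.attrs["slab_thickness"]),
            frame_times=g["frame_times"][()],
            params=_read_params(g),
            domain=str(g.attrs["domain"]),
            spectral_domain=str(g.attrs["spectral_domain"]),
            provenance=tuple(json.loads(g.attrs.get("provenance", "[]"))),
        )


def write_trace_csv(path, traces: list[KineticTrace]) -> None:
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "name": tr.name, "time": tr.times, "value": tr.values,
            "time_unit": tr.time_unit, "units": tr.units,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def read_trace_csv(path) -> list[KineticTrace]:
    df = pd.read_csv(path)
    out = []
    for name, sub in df.groupby("name", sort=False):
        out.append(KineticTrace(
            name=str(name), times=sub["time"].to_numpy(), values=sub["value"].to_numpy(),
            time_unit=str(sub["time_unit"].iloc[0]), units=str(sub["units"].iloc[0]),
        ))
    return out


# ----------------------------------------------------------------------------
# pipeline stages
# ----------------------------------------------------------------------------

def preprocess_series(fid: FIDSeries, config: RunConfig) -> SpectrumSeries:
    """Standard chain for a non-localized series.

    truncate dead time -> SVD denoise (time domain; unitary-equivalent to
    denoising the spectra) -> backward-LP restoration of the truncated head
    (undoing the time-origin shift that no first-order phase ramp can fix at
    this digitization) -> forward LP extension -> FT -> entropy phasing ->
    Whittaker baseline.
    """
    n_skip = min(config.dead_time_points, fid.n_points - 1)
    fid = preprocess.truncate_dead_time(fid, n_skip)
    rank = min(config.matrix_rank, min(fid.data.shape))
    fid = fid.with_data(denoise.svd_denoise(fid.data, rank), f"svd_denoise(r={rank})")
    if n_skip > 0 and config.lp_order < fid.n_points / 2:
        fid = preprocess.lp_restore_head(fid, n_skip, order=config.lp_order)
    if config.lp_n_out > fid.n_points and config.lp_order < fid.n_points / 2:
        fid = preprocess.flp_extend(fid, order=config.lp_order, n_out=config.lp_n_out)
    spec = preprocess.entropy_min_phase(preprocess.to_spectrum(fid))
    spec, _ = preprocess.whittaker_baseline(spec, lam=config.whittaker_lambda)
    return spec


def _window(config: RunConfig, name: str) -> PeakWindow:
    w = config.windows[name]
    return PeakWindow(name, w.center, w.half_width)


def run_pipeline(config: RunConfig, source: str | Path = "simulate", outdir: str | Path = "results") -> dict:
    """Run the full analysis and write the result bundle to ``outdir``.

    ``source`` is either the string ``"simulate"`` (generate a phantom from
    the config) or a path to an HDF5 container with ``/fid`` and optionally
    ``/csi`` groups.  Returns the fit report dictionary (also written to
    ``report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    t_start = time.time()
    timings: dict[str, float] = {}
    params = AcquisitionParams(dead_time_points=config.dead_time_points)

    def tic(stage):
        timings[stage] = time.time()

    def toc(stage):
        timings[stage] = round(time.time() - timings[stage], 3)
        log.info("stage %s finished in %.2f s", stage, timings[stage])

    tic("input")
    truth = None
    csi = None
    if str(source) == "simulate":
        truth = synthetic.make_phantom(
            config.grid, {}, noise_sigma=config.noise_sigma, seed=config.seed,
            phase0=config.phase0, phase1=config.phase1,
            baseline_coeffs=config.baseline_coeffs,
        )
        fid = synthetic.simulate_glucose_series(
            truth, params, duration=config.duration_s, frame_spacing=config.frame_spacing_s
        )
        csi = synthetic.simulate_csi(
            truth, params, n_frames=config.csi_n_frames,
            frame_spacing=config.csi_frame_spacing_s,
        )
    else:
        source = Path(source)
        if not source.exists():
            raise FileNotFoundError(f"input container {source} does not exist")
        fid = read_fid(source)
        try:
            csi = read_csi(source)
        except KeyError:
            csi = None
    toc("input")

    tic("preprocess")
    spec = preprocess_series(fid, config)
    toc("preprocess")

    tic("fit")
    glc_trace = kinetics.integrate_peak(spec, _window(config, "glucose"))
    lac_trace = kinetics.integrate_peak(spec, _window(config, "lactate"))
    report: dict = {"config_hash": chash, "seed": config.seed, "fits": {}}
    uptake = kinetics.fit_glucose_uptake(glc_trace, t0=config.t0_min)
    util = kinetics.fit_glucose_utilization(glc_trace, t_start=config.decay_start_min)
    lac_rate, lac_max, lac_info = kinetics.fit_lactate_formation(lac_trace)
    report["fits"]["glucose_uptake"] = {
        "s_total": uptake.s_total, "b": uptake.b, "k_trans_per_min": uptake.k_trans,
        "r_squared": uptake.r_squared, "flags": list(uptake.flags),
    }
    report["fits"]["glucose_utilization"] = {
        "k_util_per_min": util.k_util, "r_squared": util.r_squared, "flags": list(util.flags),
    }
    report["fits"]["lactate_formation"] = {
        "rate_per_min": lac_rate, "l_max": lac_max, "r_squared": lac_info.r_squared,
    }
    report["fits"]["glucose_lactate_ratio"] = kinetics.glucose_lactate_ratio(glc_trace, lac_trace)
    toc("fit")

    maps: dict[str, np.ndarray] = {}
    if csi is not None:
        tic("imaging")
        img = imaging.csi_reconstruct(csi)  # native grid for fitting
        img = imaging.csi_to_spectra(img)
        img = denoise.hooi_denoise(img, ranks=config.tensor_ranks)
        noise_w = _window(config, "noise")
        gmap = imaging.rate_map(img, _window(config, "glucose"), "glucose",
                                noise_window=noise_w, t_start=config.decay_start_min,
                                snr_min=config.snr_min)
        lmap = imaging.rate_map(img, _window(config, "lactate"), "lactate",
                                noise_window=noise_w, snr_min=config.snr_min)
        display = imaging.csi_reconstruct(csi, zero_fill_to=config.zero_fill)
        contour = imaging.peak_contour_map(
            imaging.csi_to_spectra(display), _window(config, "glucose"), time_average=True
        )
        maps = {
            "glucose_rate": gmap.values, "glucose_mask": gmap.mask,
            "lactate_rate": lmap.values, "lactate_mask": lmap.mask,
            "glucose_contour_timeavg": contour,
        }
        report["maps"] = {
            "glucose_rate_median_per_min": float(np.nanmedian(gmap.values[gmap.mask]))
            if gmap.mask.any() else None,
            "lactate_rate_median_per_min": float(np.nanmedian(lmap.values[lmap.mask]))
            if lmap.mask.any() else None,
            "n_fitted_voxels": int(gmap.mask.sum()),
        }
        toc("imaging")

    if truth is not None:
        report["truth"] = {
            "k_util_per_min": float(np.median(truth.maps["k_util"][truth.tumor_mask])),
            "k_trans_per_min": float(np.median(truth.maps["k_trans"][truth.tumor_mask])),
            "lac_rate_per_min": float(np.median(truth.maps["lac_rate"][truth.tumor_mask])),
        }

    tic("write")
    write_container(outdir / "container.h5", fid=fid, spectra=spec, csi=csi,
                    maps=maps, config_hash=chash, seed=config.seed)
    write_trace_csv(outdir / "traces.csv", [glc_trace, lac_trace])
    report["timings_s"] = timings
    stable = {k: v for k, v in report.items() if k != "timings_s"}
    with open(outdir / "report.json", "w") as fh:
        json.dump(stable, fh, indent=2, sort_keys=True)
    with open(outdir / "run.log", "w") as fh:
        fh.write(json.dumps({"config_hash": chash, "seed": config.seed,
                             "timings_s": timings}, indent=2, sort_keys=True))
    config.to_yaml(outdir / "config.yaml")
    toc("write")
    log.info("pipeline finished in %.2f s", time.time() - t_start)
    return report
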