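"""Deterministic synthetic inputs for testing and demos.

Provides parameterized traveling-wave kymographs and midline series
(known wavelength, frequency and amplitude gradient), circular and
straight center-of-mass paths, and the two committed demo genotypes: an
isolated-unit oscillator (stage-1 product) and a locomoting worm
(stage-2 product). The demo genotypes were produced by the package's
own evolutionary search (see ``scripts/make_demo_genotypes.py``) and are
shipped as named-slot JSON so every analysis can run without re-evolving.
"""
from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path

import numpy as np

from .analysis import Kymograph
from .circuit import Genotype


def demo_oscillator_genotype() -> Genotype:
    """Stage-1 product: isolated unit with rhythmic B-class output."""
    text = resources.files("wormcpg.data").joinpath("demo_oscillator.json").read_text()
    return Genotype.from_json(text)


def demo_locomotor_genotype() -> Genotype:
    """Stage-2 product: embodied worm crawling forward on agar."""
    text = resources.files("wormcpg.data").joinpath("demo_locomotor.json").read_text()
    return Genotype.from_json(text)


def traveling_wave_curvature(
    wavelength_bl: float = 0.6,
    frequency: float = 0.44,
    amplitude: float = 6e3,
    ap_gradient: float = 0.0,
    duration: float = 10.0,
    dt: float = 0.05,
    n_body: int = 49,
    direction: int = +1,
) -> Kymograph:
    """Analytic posterior-traveling curvature wave.

    kappa(s, t) = A(s) sin(2*pi*(f*t - direction*s/lambda)), with A(s)
    decreasing head to tail at relative rate ``ap_gradient`` (per body
    length). Amplitude in 1/m; direction +1 travels head->tail. Body
    points sit at the interior points of an (n_body+2)-point midline so
    that :func:`midlines_from_curvature` round-trips exactly.
    """
    s = (np.arange(n_body) + 1.0) / (n_body + 1.0)
    t = np.arange(0.0, duration, dt)
    A = amplitude * (1.0 - ap_gradient * (s - 0.0))
    kap = A[:, None] * np.sin(2 * np.pi * (frequency * t[None, :]
                                           - direction * s[:, None] / wavelength_bl))
    return Kymograph(curvature=kap, body_coord=s, times=t)


def midlines_from_curvature(kym: Kymograph, body_length: float = 1e-3) -> np.ndarray:
    """(n_t, n_body+1, 2) midlines whose curvature reproduces the kymograph.

    The heading angle is the arclength integral of curvature; positions
    integrate the heading. Inverts the curvature estimator up to
    discretization error, so round-trip tests are meaningful.
    """
    n_body = len(kym.body_coord)
    ds = body_length / (n_body + 1)
    mids = np.zeros((len(kym.times), n_body + 2, 2))
    for j in range(len(kym.times)):
        # one heading per segment; the turn at interior point k is kappa_k * ds
        heading = np.concatenate([[0.0], np.cumsum(kym.curvature[:, j] * ds)])
        seg = ds * np.column_stack([np.cos(heading), np.sin(heading)])
        mids[j, 1:] = np.cumsum(seg, axis=0)
    return mids


def circular_path(
    radius: float = 1e-3, speed: float = 0.22e-3, duration: float = 30.0, dt: float = 0.1
) -> np.ndarray:
    """COM path moving at constant speed on a circle of given radius (m)."""
    t = np.arange(0.0, duration, dt)
    ang = speed * t / radius
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])


def straight_path(
    speed: float = 0.22e-3, duration: float = 30.0, dt: float = 0.1, heading: float = 0.3
) -> np.ndarray:
    t = np.arange(0.0, duration, dt)
    return np.column_stack([speed * t * np.cos(heading), speed * t * np.sin(heading)])


@dataclasses.dataclass
class FixtureSet:
    """Bundle of synthetic inputs generated by :func:`generate_fixtures`."""

    seed: int
    kymographs: dict[str, Kymograph]
    midlines: dict[str, np.ndarray]
    paths: dict[str, np.ndarray]
    genotypes: dict[str, Genotype]


def generate_fixtures(seed: int = 0) -> FixtureSet:
    """Deterministic fixture set: same seed, byte-identical outputs.

    The synthetic kymographs/paths are analytic; the demo genotypes are
    the committed evolution products.
    """
    kym_pass = traveling_wave_curvature(wavelength_bl=0.6, ap_gradient=0.4)
    kym_long = traveling_wave_curvature(wavelength_bl=1.5, ap_gradient=0.4)
    kym_flat = traveling_wave_curvature(wavelength_bl=0.6, ap_gradient=0.0)
    kym_anterior = traveling_wave_curvature(wavelength_bl=0.6, ap_gradient=0.4, direction=-1)
    return FixtureSet(
        seed=seed,
        kymographs={
            "pass": kym_pass,
            "long_wavelength": kym_long,
            "flat_profile": kym_flat,
            "anterior_wave": kym_anterior,
        },
        midlines={name: midlines_from_curvature(k)
                  for name, k in (("pass", kym_pass), ("long_wavelength", kym_long))},
        paths={
            "straight": straight_path(),
            "circle_1mm": circular_path(radius=1e-3),
            "circle_half_mm": circular_path(radius=0.5e-3),
        },
        genotypes={
            "oscillator": demo_oscillator_genotype(),
            "locomotor": demo_locomotor_genotype(),
        },
    )


def write_fixtures(fixtures: FixtureSet, outdir: str | Path) -> list[Path]:
    """Write a fixture set to disk (CSV matrices + JSON genotypes)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, kym in fixtures.kymographs.items():
        p = out / f"kymograph_{name}.csv"
        np.savetxt(p, kym.curvature, delimiter=",")
        written.append(p)
    for name, path_arr in fixtures.paths.items():
        p = out / f"path_{name}.csv"
        np.savetxt(p, path_arr, delimiter=",")
        written.append(p)
    for name, g in fixtures.genotypes.items():
        p = out / f"genotype_{name}.json"
        g.to_json(p)
        written.append(p)
    meta = out / "fixtures.json"
    meta.write_text(json.dumps({"seed": fixtures.seed,
                                "files": [f.name for f in written]}, indent=1))
    written.append(meta)
    return written
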