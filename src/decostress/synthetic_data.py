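"""Seeded generators for synthetic cohorts and R-R tachograms.

The study's volunteer data are not released, so every pipeline stage is
exercised on synthetic inputs with the same statistical structure:

* a cohort of per-subject marker post/pre ratios (log-normal — ratios of
  positive quantities are right-skewed) whose SDNN ratio is a smooth planted
  function of the normalized markers plus Gaussian noise;
* R-R tachograms that are a mean heart period plus sinusoidal components at
  chosen band frequencies plus white noise, so spectral estimators can be
  checked against known band content.

Everything is reproducible from the spec's seed, and ground truth (planted
function parameters, noiseless responses) is returned alongside the data so
recovery tests can be sharp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .rbf_model import MARKER_NAMES, RatioTable, design_matrix
from .rr_processing import RRSeries

PLANTED_FUNCTIONS = ("linear", "rbf", "sinusoidal-mix")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic marker-ratio cohort.

    Marker ratios are i.i.d. log-normal with the given location/scale (on the
    log scale) per marker. The SDNN ratio is ``baseline +
    planted_function(normalized markers) + N(0, noise_sd)``.
    """

    n_subjects: int = 47
    predictor_names: tuple[str, ...] = MARKER_NAMES
    log_location: float = 0.0
    log_scale: float = 0.4
    planted_function: str = "rbf"
    noise_sd: float = 0.05
    baseline: float = 1.0  # centers SDNN ratios near "no change"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.planted_function not in PLANTED_FUNCTIONS:
            raise ValueError(f"planted_function must be one of {PLANTED_FUNCTIONS}")


@dataclass(frozen=True)
class TachogramSpec:
    """Recipe for a synthetic R-R series: mean + sinusoids + white noise."""

    n_beats: int = 2048
    mean_rr: float = 800.0  # ms
    components: tuple[tuple[float, float], ...] = ()  # (frequency Hz, amplitude ms)
    noise_sd: float = 0.0  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beats < 2:
            raise ValueError("need at least 2 beats")
        total_amp = sum(a for _, a in self.components)
        if self.mean_rr <= total_amp + 3.0 * self.noise_sd:
            raise ValueError(
                "mean_rr must exceed total amplitude + 3*noise_sd to keep intervals positive"
            )
        nyquist = 0.5 / (self.mean_rr / 1000.0)
        for freq, amp in self.components:
            if not 0.0 < freq < nyquist:
                raise ValueError(
                    f"component frequency {freq} Hz outside (0, {nyquist:.3g}) Hz"
                )
            if amp < 0:
                raise ValueError("amplitudes must be >= 0")


def _planted(spec: CohortSpec, g: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Evaluate the planted smooth function on normalized markers in [0,1]^n."""
    n_dims = g.shape[1]
    if spec.planted_function == "linear":
        coefs = rng.uniform(-0.3, 0.3, size=n_dims)
        truth = {"kind": "linear", "coefficients": coefs.tolist()}
        return g @ coefs, truth
    if spec.planted_function == "rbf":
        # in-model target: 3 Gaussian bumps, widths typical of unit-cube data
        centroids = rng.uniform(0.0, 1.0, size=(3, n_dims))
        weights = rng.uniform(-0.4, 0.4, size=3)
        sigma = 0.5 * np.sqrt(n_dims) / np.sqrt(6.0)
        theta = design_matrix(g, centroids, sigma)
        truth = {
            "kind": "rbf",
            "centroids": centroids.tolist(),
            "weights": weights.tolist(),
            "sigma": float(sigma),
        }
        return theta[:, :-1] @ weights, truth
    # sinusoidal-mix: out-of-model smooth target to probe misspecification
    freqs = rng.uniform(0.5, 1.5, size=n_dims)
    phases = rng.uniform(0.0, 2 * np.pi, size=n_dims)
    amps = rng.uniform(-0.2, 0.2, size=n_dims)
    truth = {
        "kind": "sinusoidal-mix",
        "frequencies": freqs.tolist(),
        "phases": phases.tolist(),
        "amplitudes": amps.tolist(),
    }
    return np.sin(2 * np.pi * g * freqs + phases) @ amps, truth


def generate_cohort(spec: CohortSpec) -> tuple[RatioTable, dict]:
    """Draw a synthetic cohort and return it with its ground truth.

    The ground-truth dict contains the planted-function parameters, the
    normalization bounds used, the noiseless responses, and any positivity
    shift applied — enough to recompute the planted responses independently.
    """
    rng = np.random.default_rng(spec.seed)
    n, names = spec.n_subjects, spec.predictor_names
    raw = rng.lognormal(spec.log_location, spec.log_scale, size=(n, len(names)))
    mins, maxs = raw.min(axis=0), raw.max(axis=0)
    g = (raw - mins) / (maxs - mins)

    signal, truth = _planted(spec, g, rng)
    noiseless = spec.baseline + signal
    response = noiseless + rng.normal(0.0, spec.noise_sd, size=n)
    # keep SDNN ratios strictly positive; shift only when a draw crosses zero
    shift = 0.0
    floor = float(response.min())
    if floor <= 0:
        shift = 0.01 - floor
        response = response + shift

    table = RatioTable(
        subject_ids=tuple(f"S{i + 1:03d}" for i in range(n)),
        predictors=pd.DataFrame(raw, columns=list(names)),
        response=response,
    )
    truth.update(
        baseline=spec.baseline,
        noise_sd=spec.noise_sd,
        positivity_shift=shift,
        normalization_mins=mins.tolist(),
        normalization_maxs=maxs.tolist(),
        noiseless_response=(noiseless + shift).tolist(),
        seed=spec.seed,
    )
    return table, truth


def generate_tachogram(
    spec: TachogramSpec, subject_id: str = "synthetic", phase: str = "pre"
) -> RRSeries:
    """Generate an R-R series: RR_i = mean + sum_c amp_c sin(2 pi f_c t_i) + noise.

    ``t_i`` is the cumulative time of beat i (sum of the preceding intervals),
    so a component at 0.1 Hz genuinely oscillates ten seconds per cycle.
    """
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_beats) if spec.noise_sd else None
    intervals = np.empty(spec.n_beats)
    t = 0.0  # seconds
    for i in range(spec.n_beats):
        rr = spec.mean_rr
        for freq, amp in spec.components:
            rr += amp * np.sin(2 * np.pi * freq * t)
        if noise is not None:
            rr += noise[i]
        intervals[i] = rr
        t += rr / 1000.0
    return RRSeries(subject_id=subject_id, phase=phase, intervals=intervals)


def write_fixtures(
    outdir: str | Path,
    cohort_specs: Sequence[CohortSpec] = (),
    tachogram_specs: Sequence[TachogramSpec] = (),
) -> dict:
    """Write marker CSVs and R-R text files plus a JSON manifest.

    Re-running with the same specs reproduces byte-identical files; the
    manifest records every file, its generating spec and the ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"cohorts": [], "tachograms": []}

    for i, spec in enumerate(cohort_specs):
        table, truth = generate_cohort(spec)
        path = outdir / f"cohort_{i:02d}_seed{spec.seed}.csv"
        frame = table.predictors.copy()
        frame.insert(0, "subject", list(table.subject_ids))
        frame["sdnn_ratio"] = table.response
        frame.to_csv(path, index=False, float_format="%.12g")
        manifest["cohorts"].append(
            {"file": path.name, "spec": _spec_dict(spec), "ground_truth": truth}
        )

    for i, spec in enumerate(tachogram_specs):
        series = generate_tachogram(spec)
        path = outdir / f"tachogram_{i:02d}_seed{spec.seed}.txt"
        path.write_text("".join(f"{v:.6f}\n" for v in series.intervals))
        manifest["tachograms"].append({"file": path.name, "spec": _spec_dict(spec)})

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _spec_dict(spec) -> dict:
    from dataclasses import asdict

    d = asdict(spec)
    if "components" in d:
        d["components"] = [list(c) for c in d["components"]]
    return d
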