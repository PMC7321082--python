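"""Repeated K-fold cross-validation and spectral error diagnostics.

Model quality is assessed out-of-sample only: the data are randomly
partitioned into K folds, the network is trained on K-1 folds and
scored on the held-out fold, rotating so every sample is tested exactly
once per repetition; the whole partition is redrawn for each
repetition.  The default protocol is five folds with five repetitions
(an 80:20 split, 25 fold evaluations).

Beyond the fold MSEs the module provides learning curves over
in-sample size, peak-position/intensity parity with pooled coefficients
of determination, centile ranking of per-sample errors, and the
encoded-radius / required-dimension histograms that characterise what a
fixed-size Coulomb matrix can see of each environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks
from scipy.stats import rankdata

from . import model as mlp
from .featurise import max_encoded_radius, required_cm_dimension
from .spectra import Spectrum
from .structures import AtomicCluster

__all__ = [
    "CVConfig",
    "EvaluationReport",
    "kfold_evaluate",
    "learning_curve_samples",
    "find_peaks",
    "peak_parity",
    "ParityResult",
    "centile_rank",
    "radius_histograms",
    "RadiusHistograms",
]


@dataclass(frozen=True)
class CVConfig:
    """K-fold protocol: ``k`` folds, ``repetitions`` independent partitions."""

    k: int = 5
    repetitions: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class EvaluationReport:
    """Per-fold scores plus any derived diagnostics."""

    fold_mses: pd.DataFrame  # columns: repetition, fold, mse, n_test
    per_sample_mse: np.ndarray  # pooled over folds/reps, aligned to input rows
    mean: float = 0.0
    sd: float = 0.0
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.fold_mses["mse"].to_numpy(dtype=float)
        self.mean = float(vals.mean())
        # sample standard deviation over fold MSEs
        self.sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    def to_text(self) -> str:
        lines = [
            "# cross-validation report",
            *(f"# {k}={v}" for k, v in self.settings.items()),
            f"mean_mse\t{self.mean:.8g}",
            f"sd_mse\t{self.sd:.8g}",
            f"n_folds\t{len(self.fold_mses)}",
            "",
            self.fold_mses.to_csv(sep="\t", index=False).rstrip(),
        ]
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())


def _partition(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """One random partition of ``range(n)`` into k folds of near-equal size."""
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def kfold_evaluate(
    features: np.ndarray,
    targets: np.ndarray,
    model_config: mlp.MLPConfig,
    cv: CVConfig | None = None,
    epochs: int | None = None,
) -> EvaluationReport:
    """Repeated K-fold cross-validation of the MLP.

    For every repetition a fresh random partition is drawn; within it
    each fold serves as the out-of-sample set once.  Fold model seeds
    are spawned deterministically from ``cv.seed``, so the whole run is
    reproducible bit for bit.  ``epochs`` caps training length per fold
    (defaults to the model config's ``max_epochs``).
    """
    cv = cv or CVConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    n = x.shape[0]
    if n < cv.k:
        raise ValueError(f"need at least k={cv.k} samples, got {n}")

    seed_seq = np.random.SeedSequence(cv.seed)
    part_seeds = seed_seq.spawn(cv.repetitions)
    rows = []
    per_sample_sum = np.zeros(n)
    per_sample_count = np.zeros(n)
    for rep in range(cv.repetitions):
        rng = np.random.default_rng(part_seeds[rep])
        folds = _partition(n, cv.k, rng)
        for fold_i, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            fold_seed = int(
                np.random.SeedSequence(
                    [cv.seed, rep, fold_i]
                ).generate_state(1)[0] % (2**31)
            )
            cfg = mlp.MLPConfig(**{**vars(model_config), "seed": fold_seed})
            net = mlp.build(cfg)
            mlp.train(net, x[train_idx], y[train_idx], epochs=epochs)
            pred = mlp.predict(net, x[test_idx])
            per_sample, fold_mse = mlp.mse(pred, y[test_idx])
            per_sample_sum[test_idx] += per_sample
            per_sample_count[test_idx] += 1
            rows.append(
                {"repetition": rep, "fold": fold_i, "mse": fold_mse,
                 "n_test": len(test_idx)}
            )
    per_sample = per_sample_sum / np.maximum(per_sample_count, 1)
    report = EvaluationReport(
        pd.DataFrame(rows), per_sample,
        settings={
            "k": cv.k, "repetitions": cv.repetitions, "seed": cv.seed,
            "epochs": epochs if epochs is not None else model_config.max_epochs,
            "model": f"{model_config.layer_sizes}",
        },
    )
    return report


def learning_curve_samples(
    features: np.ndarray,
    targets: np.ndarray,
    sizes: list[int],
    model_config: mlp.MLPConfig,
    cv: CVConfig | None = None,
    epochs: int | None = None,
) -> pd.DataFrame:
    """Mean out-of-sample MSE as a function of dataset size.

    For each requested size a seeded subsample (without replacement) is
    drawn and cross-validated; the curve rows are (size, mean MSE, sd).
    """
    cv = cv or CVConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    n = x.shape[0]
    rows = []
    for size_i, size in enumerate(sizes):
        if size > n:
            raise ValueError(f"requested size {size} exceeds {n} samples")
        if size == n:
            idx = np.arange(n)
        else:
            rng = np.random.default_rng(
                np.random.SeedSequence([cv.seed, 7919, size_i])
            )
            idx = np.sort(rng.choice(n, size=size, replace=False))
        rep = kfold_evaluate(x[idx], y[idx], model_config, cv, epochs=epochs)
        rows.append({"n_samples": size, "mean_mse": rep.mean, "sd_mse": rep.sd})
    return pd.DataFrame(rows)


def find_peaks(
    spectrum: Spectrum, prominence_fraction: float = 0.05
) -> list[tuple[float, float]]:
    """Prominence-filtered local maxima of a (broadened) spectrum.

    Returns (energy, intensity) pairs sorted by energy; the prominence
    threshold is the given fraction of the global maximum, so a flat or
    monotone spectrum yields no peaks.
    """
    y = spectrum.intensities
    if len(y) < 3 or y.max() <= 0:
        return []
    idx, _ = _scipy_find_peaks(y, prominence=prominence_fraction * y.max())
    return [(float(spectrum.energies[i]), float(y[i])) for i in idx]


@dataclass
class ParityResult:
    """Pooled target/estimate peak pairs and their R^2 values."""

    pairs: pd.DataFrame  # columns: sample, e_target, e_est, i_target, i_est
    r2_energy: float | None
    r2_intensity: float | None
    n_unmatched_target: int
    n_unmatched_estimate: int
    settings: dict = field(default_factory=dict)


def _r2(a: np.ndarray, b: np.ndarray, method: str) -> float | None:
    if len(a) < 2:
        return None
    if method == "pearson":
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return None
        r = np.corrcoef(a, b)[0, 1]
        return float(r**2)
    if method == "identity":
        ss_tot = float(np.sum((a - a.mean()) ** 2))
        if ss_tot == 0:
            return None
        return float(1.0 - np.sum((a - b) ** 2) / ss_tot)
    raise ValueError(f"unknown r2 method {method!r}")


def peak_parity(
    targets: list[Spectrum],
    estimates: list[Spectrum],
    window: float = 5.0,
    prominence_fraction: float = 0.05,
    r2_method: str = "pearson",
) -> ParityResult:
    """Match target and estimated peaks and pool them into parity R^2.

    Per sample, each target peak is greedily matched (in energy order)
    to the nearest unused estimated peak within ``window`` eV.  The
    pooled pair lists give one R^2 for peak energies and one for peak
    intensities; with fewer than two pairs R^2 is reported as
    unavailable (None).
    """
    if len(targets) != len(estimates):
        raise ValueError("targets and estimates must pair row-for-row")
    rows = []
    unmatched_t = unmatched_e = 0
    for si, (t, e) in enumerate(zip(targets, estimates)):
        pt = find_peaks(t, prominence_fraction)
        pe = find_peaks(e, prominence_fraction)
        used = [False] * len(pe)
        for et, it in pt:
            best, best_d = None, window
            for j, (ee, ie) in enumerate(pe):
                d = abs(ee - et)
                if not used[j] and d <= best_d:
                    best, best_d = j, d
            if best is None:
                unmatched_t += 1
                continue
            used[best] = True
            ee, ie = pe[best]
            rows.append(
                {"sample": si, "e_target": et, "e_est": ee,
                 "i_target": it, "i_est": ie}
            )
        unmatched_e += used.count(False)
    pairs = pd.DataFrame(
        rows, columns=["sample", "e_target", "e_est", "i_target", "i_est"]
    )
    r2_e = _r2(pairs["e_target"].to_numpy(), pairs["e_est"].to_numpy(), r2_method)
    r2_i = _r2(pairs["i_target"].to_numpy(), pairs["i_est"].to_numpy(), r2_method)
    return ParityResult(
        pairs, r2_e, r2_i, unmatched_t, unmatched_e,
        settings={
            "window_eV": window,
            "prominence_fraction": prominence_fraction,
            "r2_method": r2_method,
        },
    )


def centile_rank(per_sample_mse: np.ndarray) -> np.ndarray:
    """Centile of each sample when ranked by MSE ascending.

    Centile 1 holds the best-predicted samples, centile 100 the worst;
    ties share a centile (minimum-rank convention).  With exactly 100
    distinct scores each centile holds one sample.
    """
    scores = np.asarray(per_sample_mse, dtype=float)
    n = len(scores)
    if n == 0:
        return np.array([], dtype=int)
    ranks = rankdata(scores, method="min")
    return np.ceil(100.0 * ranks / n).astype(int)


@dataclass
class RadiusHistograms:
    """Normalised histograms of CM reach and required CM dimension."""

    radius_edges: np.ndarray
    radius_density: np.ndarray
    radius_mode: float  # centre of the modal bin
    dimension_edges: np.ndarray
    dimension_density: np.ndarray
    dimension_mode: float


def radius_histograms(
    clusters: list[AtomicCluster],
    n: int = 20,
    radius: float = 4.0,
    bins: int = 30,
) -> RadiusHistograms:
    """Characterise a dataset's local environments for CM featurisation.

    Histogram (a): the maximum radius a CM of dimension ``n`` encodes
    around each absorber (distance to the n-th nearest atom).
    Histogram (b): the CM dimension required to encode everything
    within ``radius``.  Both are normalised to unit area.
    """
    if not clusters:
        raise ValueError("cluster list is empty")
    radii = np.array([max_encoded_radius(c, n) for c in clusters])
    dims = np.array([required_cm_dimension(c, radius) for c in clusters])

    # near-degenerate spreads (identical clusters) get a fixed 1 A window
    if radii.max() - radii.min() < 1e-6:
        r_range = (radii.mean() - 0.5, radii.mean() + 0.5)
    else:
        r_range = (radii.min(), radii.max())
    r_density, r_edges = np.histogram(
        radii, bins=bins, range=r_range, density=True
    )
    d_lo, d_hi = dims.min(), dims.max()
    d_edges = np.arange(d_lo - 0.5, d_hi + 1.5)
    d_density, d_edges = np.histogram(dims, bins=d_edges, density=True)

    def _mode(density, edges):
        i = int(np.argmax(density))
        return float(0.5 * (edges[i] + edges[i + 1]))

    return RadiusHistograms(
        r_edges, r_density, _mode(r_density, r_edges),
        d_edges, d_density, _mode(d_density, d_edges),
    )
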