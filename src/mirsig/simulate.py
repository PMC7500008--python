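"""Seeded synthetic miRNA-seq datasets with known ground truth.

The generator emulates the statistical structure the pipeline assumes for a
two-cohort (N0/N1) miRNA-seq study: negative-binomial counts over ~300
expressed miRNAs, log-normal library sizes, and two anti-correlated
signature modules (9 miRNAs up in N1, 9 down in N1) driven by a shared
per-sample latent factor that is shifted in the N1 cohort.  Because the
modules respond to one latent variable rather than to independent group
shifts, their members are mutually correlated (and cross-anticorrelated)
*within* cohorts as well as between them — the correlation structure the
signature analysis is designed to detect.  Optional composition bias
multiplies a fraction of non-signature miRNAs in N1 samples only, creating
the TMM-versus-total-count divergence probed by the normalization
comparison.

Default cohort sizes are 24 N0 + 20 N1 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SpecValidationError
from .io import CountMatrix, Dataset, SampleAnnotation

__all__ = ["SyntheticSpec", "GroundTruth", "generate_dataset", "truth_evaluation", "write_truth"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``effect_beta`` is the shift (log2 units) of the latent factor in N1
    samples; ``latent_sd`` its within-cohort spread; ``dispersion`` the NB
    overdispersion phi in Var = mu + phi mu^2 (0 degenerates to Poisson).
    ``composition_bias``, when given, is a (fraction, fold) pair applied to
    non-signature miRNAs in N1 samples only.
    """

    n_mirnas: int = 300
    n_N0: int = 24
    n_N1: int = 20
    n_up: int = 9
    n_down: int = 9
    effect_beta: float = 1.0
    latent_sd: float = 0.5
    dispersion: float | Sequence[float] = 0.3
    lib_size_log_mean: float = float(np.log(2e6))
    lib_size_log_sd: float = 0.3
    composition_bias: tuple[float, float] | None = None
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up < 0 or self.n_down < 0 or self.n_up + self.n_down > self.n_mirnas:
            raise SpecValidationError("n_up + n_down must not exceed n_mirnas (both >= 0)")
        if self.n_N0 < 2 or self.n_N1 < 2:
            raise SpecValidationError("each cohort needs at least 2 samples (n_N0, n_N1)")
        for name in ("latent_sd", "lib_size_log_sd", "baseline_log_sd"):
            if getattr(self, name) < 0:
                raise SpecValidationError(f"{name} must be >= 0")
        disp = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        if (disp < 0).any():
            raise SpecValidationError("dispersion must be >= 0")
        if disp.size not in (1, self.n_mirnas):
            raise SpecValidationError("dispersion must be scalar or one value per miRNA")
        if self.composition_bias is not None:
            frac, fold = self.composition_bias
            if not 0 <= frac <= 1 or fold <= 0:
                raise SpecValidationError("composition_bias is (fraction in [0,1], fold > 0)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SpecValidationError(f"unknown spec fields: {sorted(unknown)}")
        if "composition_bias" in raw and raw["composition_bias"] is not None:
            raw["composition_bias"] = tuple(raw["composition_bias"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if d["composition_bias"] is not None:
            d["composition_bias"] = list(d["composition_bias"])
        d["dispersion"] = (
            float(d["dispersion"])
            if np.ndim(d["dispersion"]) == 0
            else [float(v) for v in d["dispersion"]]
        )
        for k in ("lib_size_log_mean", "lib_size_log_sd", "latent_sd", "effect_beta",
                  "baseline_log_mean", "baseline_log_sd"):
            d[k] = float(d[k])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a synthetic dataset."""

    up_set: tuple[str, ...]
    down_set: tuple[str, ...]
    latent_z: np.ndarray
    true_log2fc: pd.Series  # per-miRNA expected group log2 FC


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mu, phi) with Var = mu + phi mu^2; phi == 0 rows are Poisson."""
    out = np.empty(mu.shape, dtype=np.int64)
    poisson_rows = phi < 1e-12
    if poisson_rows.any():
        out[poisson_rows] = rng.poisson(mu[poisson_rows])
    nb_rows = ~poisson_rows
    if nb_rows.any():
        size = 1.0 / phi[nb_rows][:, None]
        p = size / (size + mu[nb_rows])
        out[nb_rows] = rng.negative_binomial(size, p)
    return out


def generate_dataset(spec: SyntheticSpec) -> tuple[Dataset, GroundTruth]:
    """Draw one dataset and its ground truth, fully reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_N0 + spec.n_N1
    width = len(str(spec.n_mirnas))
    mirna_ids = [f"miR-sim-{i + 1:0{width}d}" for i in range(spec.n_mirnas)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    node = np.array(["N0"] * spec.n_N0 + ["N1"] * spec.n_N1)
    is_n1 = node == "N1"

    signature = rng.choice(spec.n_mirnas, size=spec.n_up + spec.n_down, replace=False)
    up_idx = np.sort(signature[: spec.n_up])
    down_idx = np.sort(signature[spec.n_up :])
    delta = np.zeros(spec.n_mirnas)
    delta[up_idx] = 1.0
    delta[down_idx] = -1.0

    z = spec.effect_beta * is_n1.astype(float) + rng.normal(0.0, spec.latent_sd, n_samples)
    baseline = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_mirnas)
    p_m = baseline / baseline.sum()
    lib = rng.lognormal(spec.lib_size_log_mean, spec.lib_size_log_sd, n_samples)

    mu = lib[None, :] * p_m[:, None] * 2.0 ** (delta[:, None] * z[None, :])
    if spec.composition_bias is not None:
        frac, fold = spec.composition_bias
        null_idx = np.flatnonzero(delta == 0)
        n_biased = int(round(frac * spec.n_mirnas))
        biased = rng.choice(null_idx, size=min(n_biased, null_idx.size), replace=False)
        mu[np.ix_(biased, np.flatnonzero(is_n1))] *= fold

    phi = np.broadcast_to(np.atleast_1d(np.asarray(spec.dispersion, float)), (spec.n_mirnas,)).copy()
    counts = _nb_draw(rng, mu, phi)

    cm = CountMatrix(pd.DataFrame(counts, index=mirna_ids, columns=sample_ids))
    annotations = tuple(SampleAnnotation(s, n) for s, n in zip(sample_ids, node))
    truth = GroundTruth(
        up_set=tuple(mirna_ids[i] for i in up_idx),
        down_set=tuple(mirna_ids[i] for i in down_idx),
        latent_z=z,
        true_log2fc=pd.Series(delta * spec.effect_beta, index=mirna_ids, name="true_log2fc"),
    )
    return Dataset(cm, annotations), truth


def truth_evaluation(calls, truth: GroundTruth) -> tuple[float, float, float]:
    """Recovery metrics of a DE call set against the planted truth.

    Returns (sensitivity, observed FDR, sign accuracy over true positives);
    observed FDR is 0 when nothing was called, sign accuracy 1 when there is
    no true positive to grade.
    """
    truth_sign = {m: 1 for m in truth.up_set}
    truth_sign.update({m: -1 for m in truth.down_set})
    universe = set(truth.true_log2fc.index)
    called: dict[str, int] = {}
    for r in calls:
        if r.mirna_id not in universe:
            raise KeyError(f"called miRNA {r.mirna_id!r} not in the truth universe")
        if r.call == "N1_miR":
            called[r.mirna_id] = 1
        elif r.call == "N0_miR":
            called[r.mirna_id] = -1
    n_true = len(truth_sign)
    tp = [m for m in called if m in truth_sign]
    fp = [m for m in called if m not in truth_sign]
    sensitivity = len(tp) / n_true if n_true else float("nan")
    observed_fdr = len(fp) / len(called) if called else 0.0
    sign_acc = (
        sum(called[m] == truth_sign[m] for m in tp) / len(tp) if tp else 1.0
    )
    return sensitivity, observed_fdr, sign_acc


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Persist ground truth as TSV (mirna_id, delta, true_log2fc)."""
    delta = pd.Series(0, index=truth.true_log2fc.index, name="delta")
    delta[list(truth.up_set)] = 1
    delta[list(truth.down_set)] = -1
    df = pd.DataFrame({"delta": delta, "true_log2fc": truth.true_log2fc})
    df.to_csv(Path(path), sep="\t", index_label="mirna_id", float_format="%.6g")
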