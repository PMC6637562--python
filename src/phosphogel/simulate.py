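"""Synthetic dual-stain 2-DE spot-volume generator with known ground truth.

The generator emulates the measurement layer of a two-group (treated vs
control), four-biological-replicate dual-stain gel experiment:

* each spot has a lognormal baseline total-protein volume shared by both
  groups (spot abundances on gels are positive and right-skewed);
* each gel image (group x replicate x channel) carries a lognormal
  multiplicative factor emulating residual staining/scanning variation
  left over after image normalization;
* each individual measurement gets mean-one lognormal noise parameterized
  by a coefficient of variation;
* the phospho-channel volume of a spot is its true phosphorylation fraction
  times its baseline, so in the absence of noise P/T recovers the fraction
  exactly;
* a spot-replicate is detected with a per-spot, per-group probability;
  undetected measurements are missing rows, not zeros, so the
  reproducibility filter is exercised downstream.

Volumes are emitted on a common per-channel scale, i.e. the tables play the
role of image-normalized exports; see docs/methods.md for why re-running
total-valid-spot normalization on such data would bias PR between groups
with unequal phospho composition.

The distributional choices (lognormal everywhere) are stand-ins: no noise
model for real dual-stain spot volumes is established. What passing
recovery tests show is therefore internal consistency of the pipeline, not
fidelity to any particular scanner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, UnknownScenarioError

#: default significance ground-truth threshold on |delta phospho_fraction|
DEFAULT_SIG_THRESHOLD = 0.1


@dataclass
class SimulationConfig:
    """Full description of one synthetic dual-stain experiment.

    ``phospho_fractions`` maps each spot id to its true phosphorylation
    fraction (the noise-free PR) per group, as ``(treated, control)`` pairs.
    ``detection_prob`` is either a scalar applied everywhere or a mapping
    with the same shape. Spots unique to one group are simply spots whose
    fraction is zero in the other group.
    """

    phospho_fractions: dict[str, tuple[float, float]]
    groups: tuple[str, str] = ("DFD", "control")
    n_replicates: int = 4
    baseline_log_mean: float = 8.0
    baseline_log_sd: float = 1.0
    gel_factor_sd: float = 0.05
    noise_cv: float = 0.1
    detection_prob: float | dict[str, tuple[float, float]] = 1.0
    sig_threshold: float = DEFAULT_SIG_THRESHOLD
    seed: int = 0

    @property
    def n_spots(self) -> int:
        return len(self.phospho_fractions)

    @property
    def spot_ids(self) -> list[str]:
        return list(self.phospho_fractions)

    def detection(self, spot_id: str, group_index: int) -> float:
        if isinstance(self.detection_prob, dict):
            return self.detection_prob[spot_id][group_index]
        return self.detection_prob

    def validate(self) -> "SimulationConfig":
        if self.n_spots < 1:
            raise ConfigError("phospho_fractions: need at least one spot")
        if len(self.groups) != 2 or self.groups[0] == self.groups[1]:
            raise ConfigError("groups: need two distinct group labels")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates: must be >= 1")
        for name in ("gel_factor_sd", "noise_cv", "baseline_log_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")
        if not 0 < self.sig_threshold:
            raise ConfigError("sig_threshold: must be > 0")
        for sid, pair in self.phospho_fractions.items():
            if len(pair) != 2 or not all(0 <= f <= 1 for f in pair):
                raise ConfigError(
                    f"phospho_fractions: spot {sid} values must lie in [0, 1]")
        if isinstance(self.detection_prob, dict):
            if set(self.detection_prob) != set(self.phospho_fractions):
                raise ConfigError("detection_prob: spot ids must match phospho_fractions")
            for sid, pair in self.detection_prob.items():
                if len(pair) != 2 or not all(0 <= p <= 1 for p in pair):
                    raise ConfigError(
                        f"detection_prob: spot {sid} values must lie in [0, 1]")
        elif not 0 <= self.detection_prob <= 1:
            raise ConfigError("detection_prob: must lie in [0, 1]")
        return self

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path=None) -> str:
        doc = {
            "groups": list(self.groups),
            "n_replicates": self.n_replicates,
            "baseline_log_mean": self.baseline_log_mean,
            "baseline_log_sd": self.baseline_log_sd,
            "gel_factor_sd": self.gel_factor_sd,
            "noise_cv": self.noise_cv,
            "sig_threshold": self.sig_threshold,
            "seed": self.seed,
            "phospho_fractions": {k: list(map(float, v))
                                  for k, v in self.phospho_fractions.items()},
            "detection_prob": (
                {k: list(map(float, v)) for k, v in self.detection_prob.items()}
                if isinstance(self.detection_prob, dict) else self.detection_prob),
        }
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SimulationConfig":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        elif isinstance(source, str) and "\n" in source:
            doc = yaml.safe_load(source)
        else:  # path-like
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        doc["groups"] = tuple(doc["groups"])
        doc["phospho_fractions"] = {str(k): tuple(v)
                                    for k, v in doc["phospho_fractions"].items()}
        if isinstance(doc.get("detection_prob"), dict):
            doc["detection_prob"] = {str(k): tuple(v)
                                     for k, v in doc["detection_prob"].items()}
        return cls(**doc).validate()

    @classmethod
    def random(cls, n_spots: int, frac_phospho: float = 0.15,
               frac_unique_treated: float = 0.4, frac_unique_control: float = 0.3,
               seed: int = 0, **kwargs) -> "SimulationConfig":
        """Draw a random fraction layout: ``frac_phospho`` of spots carry
        phospho signal; of those, the given fractions are unique to one
        group; the rest share a common fraction in both groups."""
        rng = np.random.default_rng(seed)
        ids = [f"S{i + 1:03d}" for i in range(n_spots)]
        n_pos = round(n_spots * frac_phospho)
        n_ut = round(n_pos * frac_unique_treated)
        n_uc = round(n_pos * frac_unique_control)
        fractions = {}
        for i, sid in enumerate(ids):
            if i < n_ut:
                fractions[sid] = (float(rng.uniform(0.1, 0.95)), 0.0)
            elif i < n_ut + n_uc:
                fractions[sid] = (0.0, float(rng.uniform(0.1, 0.95)))
            elif i < n_pos:
                f = float(rng.uniform(0.05, 0.6))
                fractions[sid] = (f, f)
            else:
                fractions[sid] = (0.0, 0.0)
        return cls(phospho_fractions=fractions, seed=seed, **kwargs).validate()


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated experiment.

    ``per_group`` has one row per spot x group with the true phosphorylation
    fraction (the noise-free PR) and detection probability;
    ``expected_significant`` labels each spot as a true change when
    ``|fraction_treated - fraction_control| >= sig_threshold``.
    """

    per_group: pd.DataFrame
    expected_significant: pd.Series
    sig_threshold: float

    def to_csv(self, path) -> None:
        df = self.per_group.copy()
        df["expected_significant"] = df["spot_id"].map(self.expected_significant)
        df.to_csv(path, index=False)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def generate_spot_table(config: SimulationConfig):
    """Generate ``(treated_table, control_table, truth)`` for one experiment.

    Identical config and seed give byte-identical tables. With
    ``noise_cv = 0``, ``gel_factor_sd = 0`` and full detection, every
    per-replicate P/T equals the spot's true phosphorylation fraction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids = config.spot_ids
    n_spots, n_reps = config.n_spots, config.n_replicates

    baselines = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                              size=n_spots)
    # per (group, replicate, channel) residual gel factor
    gel_factors = (
        rng.lognormal(0.0, config.gel_factor_sd, size=(2, n_reps, 2))
        if config.gel_factor_sd > 0 else np.ones((2, n_reps, 2)))
    fractions = np.array([config.phospho_fractions[s] for s in ids])  # (spots, 2)
    det = np.array([[config.detection(s, g) for g in (0, 1)] for s in ids])
    detected = rng.random(size=(n_spots, 2, n_reps)) < det[:, :, None]
    noise_t = _lognormal_noise(rng, config.noise_cv, (n_spots, 2, n_reps))
    noise_p = _lognormal_noise(rng, config.noise_cv, (n_spots, 2, n_reps))

    frames = []
    for g, group in enumerate(config.groups):
        rows = []
        for r in range(n_reps):
            present = detected[:, g, r]
            for s in np.flatnonzero(present):
                t_vol = baselines[s] * gel_factors[g, r, 1] * noise_t[s, g, r]
                rows.append((ids[s], group, r + 1, "total", t_vol))
                f = fractions[s, g]
                if f > 0:
                    p_vol = f * baselines[s] * gel_factors[g, r, 0] * noise_p[s, g, r]
                    rows.append((ids[s], group, r + 1, "phospho", p_vol))
        frame = pd.DataFrame(rows, columns=["spot_id", "group", "replicate",
                                            "channel", "volume"])
        frame["present"] = True
        frames.append(frame)

    per_group = pd.DataFrame({
        "spot_id": np.repeat(ids, 2),
        "group": list(config.groups) * n_spots,
        "phospho_fraction": fractions.ravel(),
        "detection_prob": det.ravel(),
    })
    expected = pd.Series(
        {sid: bool(abs(f[0] - f[1]) >= config.sig_threshold)
         for sid, f in config.phospho_fractions.items()}, name="expected_significant")
    truth = SyntheticTruth(per_group=per_group, expected_significant=expected,
                           sig_threshold=config.sig_threshold)
    return frames[0], frames[1], truth


# ---------------------------------------------------------------------------
# presets

_T1_DFD_UNIQUE = [0.41, 0.54, 0.48, 0.36, 0.33, 0.31, 0.35, 0.31, 0.70,
                  0.69, 0.66, 0.63, 0.72, 0.71, 0.69, 0.65, 0.93, 0.94]
_T1_CONTROL_UNIQUE = [0.12, 0.12, 0.15, 0.13, 0.11, 0.37, 0.73, 0.49, 0.46,
                      0.13, 0.09, 0.38, 0.37]


def _paper_like(seed: int) -> SimulationConfig:
    """Two groups x 4 replicates, 320 spots, phospho layout mirroring a
    published DFD-vs-control bovine LT muscle comparison: 46 and 41
    phospho-positive spots (14.6% / 13.3% of ~314 / ~308 reproducible), 28
    shared, 18/13 group-unique, one shared spot with a strong change."""
    ids = [f"S{i + 1:03d}" for i in range(320)]
    fractions: dict[str, tuple[float, float]] = {}
    k = 0
    for f in _T1_DFD_UNIQUE:  # 18 treated-unique
        fractions[ids[k]] = (f, 0.0); k += 1
    for f in _T1_CONTROL_UNIQUE:  # 13 control-unique
        fractions[ids[k]] = (0.0, f); k += 1
    fractions[ids[k]] = (0.08, 0.36); k += 1  # the one shared changed spot
    for f in np.linspace(0.05, 0.60, 27):  # 27 shared null spots
        fractions[ids[k]] = (float(f), float(f)); k += 1
    for sid in ids[k:]:
        fractions[sid] = (0.0, 0.0)
    detection: dict[str, tuple[float, float]] = {sid: (0.95, 0.95) for sid in ids}
    for sid in ids[299:311]:  # 12 spots never detected in control -> ~308
        detection[sid] = (0.95, 0.0)
    for sid in ids[311:317]:  # 6 spots never detected in treated -> ~314
        detection[sid] = (0.0, 0.95)
    return SimulationConfig(phospho_fractions=fractions, detection_prob=detection,
                            noise_cv=0.1, gel_factor_sd=0.05, seed=seed).validate()


def _noise_free(seed: int) -> SimulationConfig:
    """20 spots, 5 with fraction 0.8 vs 0, no noise, full detection."""
    ids = [f"S{i + 1:03d}" for i in range(20)]
    fractions = {sid: ((0.8, 0.0) if i < 5 else (0.0, 0.0))
                 for i, sid in enumerate(ids)}
    return SimulationConfig(phospho_fractions=fractions, noise_cv=0.0,
                            gel_factor_sd=0.0, detection_prob=1.0,
                            seed=seed).validate()


def _small_recovery(seed: int) -> SimulationConfig:
    """20 spots, 5 true changes (0.8 vs 0), noise_cv 0.1, full detection."""
    cfg = _noise_free(seed)
    cfg.noise_cv = 0.1
    cfg.gel_factor_sd = 0.05
    return cfg.validate()


_PRESETS = {
    "paper_like": _paper_like,
    "noise_free": _noise_free,
    "small_recovery": _small_recovery,
}


def scenario_preset(name: str, seed: int = 0) -> SimulationConfig:
    """Return a complete, documented :class:`SimulationConfig` by name."""
    try:
        builder = _PRESETS[name]
    except KeyError:
        raise UnknownScenarioError(
            f"unknown scenario {name!r}; valid names: {sorted(_PRESETS)}") from None
    return builder(seed)
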