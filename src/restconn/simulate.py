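"""Synthetic two-group resting-state cohorts.

Generates control and patient cohorts of ROI x time series whose
population correlation structure is block compound-symmetric by
resting-state network: within-network correlations at a target r,
everything else at a background level, with the patient group's visual
network block attenuated.  This emulates the study design the analysis
expects — two groups of 10 subjects, 160 timepoints, controls with a
denser visual network — without any imaging data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .atlas import AtlasTable, NetworkDefinition, load_atlas, load_networks, resolve_members
from .connectivity import TimeSeriesMatrix
from .exceptions import ParameterError

_EIG_FLOOR = 1e-10


@dataclass
class CohortSpec:
    """Study-condition parameters for the synthetic cohort generator.

    Defaults mirror the target study design: 10 controls vs 10 patients,
    160 timepoints per subject, within-network target correlation 0.65
    for every network in both groups, background correlation 0.2, and the
    patient visual-network block attenuated by 0.5.  ``noise_sd`` adds
    white noise on top of the latent signal (0 keeps the targets exactly
    marginal); ``ar_coef`` optionally imposes AR(1) temporal smoothness
    with unchanged marginal covariance.
    """

    n_controls: int = 10
    n_patients: int = 10
    n_timepoints: int = 160
    within_network_r: float | dict = 0.65
    between_network_r: float = 0.2
    patient_vn_attenuation: float = 0.5
    vn_name: str = "VN"
    noise_sd: float = 0.0
    ar_coef: float = 0.0
    seed: int = 0
    atlas: AtlasTable = field(default_factory=load_atlas)
    networks: dict[str, NetworkDefinition] = field(default_factory=load_networks)

    def __post_init__(self) -> None:
        if not 0.0 <= self.patient_vn_attenuation <= 1.0:
            raise ParameterError("patient_vn_attenuation must lie in [0, 1]")
        if not 0.0 <= self.between_network_r < 1.0:
            raise ParameterError("between_network_r must lie in [0, 1)")
        for r in self._within_map().values():
            if not 0.0 <= r < 1.0:
                raise ParameterError("within-network targets must lie in [0, 1)")
        if not 0.0 <= abs(self.ar_coef) < 1.0:
            raise ParameterError("ar_coef must lie in (-1, 1)")
        if self.vn_name not in self.networks:
            raise ParameterError(f"network {self.vn_name!r} not defined")

    def _within_map(self) -> dict[str, float]:
        if isinstance(self.within_network_r, dict):
            return {name: float(self.within_network_r.get(name, 0.65)) for name in self.networks}
        return {name: float(self.within_network_r) for name in self.networks}

    def spec_hash(self) -> str:
        payload = {
            k: v for k, v in self.__dict__.items() if k not in ("atlas", "networks")
        }
        payload["networks"] = {n: list(d.members) for n, d in self.networks.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def build_covariance(spec: CohortSpec, group: str) -> np.ndarray:
    """Group population covariance: unit diagonal, compound-symmetric
    within-network blocks, background elsewhere.

    For the patient group the visual-network off-diagonal block is
    multiplied by ``patient_vn_attenuation``.  The result is repaired to
    positive semidefiniteness by eigenvalue flooring if needed (then
    rescaled back to unit diagonal).
    """
    if group not in ("control", "patient"):
        raise ParameterError(f"group must be 'control' or 'patient', got {group!r}")
    n = spec.atlas.n_regions
    cov = np.full((n, n), spec.between_network_r)
    within = spec._within_map()
    for name, net in spec.networks.items():
        idx = resolve_members(spec.atlas, net)
        block = np.ix_(idx, idx)
        cov[block] = within[name]
        if group == "patient" and name == spec.vn_name:
            cov[block] = within[name] * spec.patient_vn_attenuation
    np.fill_diagonal(cov, 1.0)

    eigval, eigvec = np.linalg.eigh(cov)
    if eigval.min() < 0:
        eigval = np.maximum(eigval, _EIG_FLOOR)
        cov = (eigvec * eigval) @ eigvec.T
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        if np.linalg.eigvalsh(cov).min() < -1e-9:
            raise ParameterError("correlation targets produce a non-repairable covariance")
    return cov


def _draw_subject(
    rng: np.random.Generator, chol: np.ndarray, spec: CohortSpec
) -> np.ndarray:
    """One ROI x time draw; AR(1) innovations keep the marginal covariance."""
    n = chol.shape[0]
    t = spec.n_timepoints
    z = rng.standard_normal((t, n))
    if spec.ar_coef:
        phi = spec.ar_coef
        out = np.empty_like(z)
        out[0] = z[0]
        scale = np.sqrt(1.0 - phi**2)
        for s in range(1, t):
            out[s] = phi * out[s - 1] + scale * z[s]
        z = out
    x = z @ chol.T
    if spec.noise_sd:
        x = x + spec.noise_sd * rng.standard_normal(x.shape)
    return x.T  # ROI x time


def simulate_cohort(spec: CohortSpec) -> dict[str, list[TimeSeriesMatrix]]:
    """Draw both cohorts; a fixed seed gives bit-identical output.

    Returns ``{"control": [...], "patient": [...]}`` of
    :class:`TimeSeriesMatrix`, subject ids HC01.. / PT01..
    """
    rng = np.random.default_rng(spec.seed)
    labels = tuple(spec.atlas.labels)
    cohorts: dict[str, list[TimeSeriesMatrix]] = {}
    for group, n_sub, prefix in (
        ("control", spec.n_controls, "HC"),
        ("patient", spec.n_patients, "PT"),
    ):
        chol = np.linalg.cholesky(build_covariance(spec, group) + _EIG_FLOOR * np.eye(len(labels)))
        cohorts[group] = [
            TimeSeriesMatrix(f"{prefix}{i + 1:02d}", _draw_subject(rng, chol, spec), labels)
            for i in range(n_sub)
        ]
    return cohorts


def write_cohort(cohort: dict[str, list[TimeSeriesMatrix]], out_dir: str | Path, spec: CohortSpec) -> Path:
    """Write one CSV per subject plus a JSON manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": spec.seed, "spec_hash": spec.spec_hash(), "subjects": []}
    for group, subjects in cohort.items():
        for ts in subjects:
            path = out / f"{ts.subject_id}.csv"
            np.savetxt(path, ts.values, delimiter=",")
            manifest["subjects"].append(
                {"subject_id": ts.subject_id, "group": group, "file": path.name}
            )
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath
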