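"""The four-node DCM model space and its neural + hemodynamic forward model.

Seven candidate motifs over the nodes IPL, rPFC, DLPFC and SFG share a
common base — driving input to the IPL, IPL->rPFC modulated by regular
trials, IPL->DLPFC modulated by different trials, and a DLPFC->IPL backward
connection — and differ in how activity reaches the SFG: serially through
both prefrontal nodes (Diamond), in parallel directly from IPL (Fork),
hierarchically with one condition's modulation at the higher level (Legs 1,
Legs 2), or through activity-dependent gating where one prefrontal region
gates the other's afferent to the SFG (Stork 1, Stork 2, and the
double-gated Stork 3).

Neural dynamics follow the one-state-per-region nonlinear DCM form

    dx/dt = (A + sum_j u_j B^(j) + sum_k x_k D^(k)) x + C u,

with self-connections a_ii = -0.5 exp(theta_self,i) < 0.  Each region's
neural state drives balloon-model hemodynamics (vasodilatory signal s, flow
f, volume v, deoxyhemoglobin q) whose output nonlinearity yields the BOLD
signal.  The exact wiring of every motif lives in ``data/model_space.json``
so alternative readings of the motifs are a config change, not a code
change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from precistim._integrator import integrate_batch

__all__ = [
    "NODES",
    "INPUTS",
    "DCMModel",
    "DCMParams",
    "HemoParams",
    "InputSet",
    "BOLDSeries",
    "build_model_space",
    "default_generating_params",
    "neural_drift",
    "hemodynamics_step",
    "bold_signal",
    "simulate_bold",
    "stability_check",
]

NODES = ("IPL", "rPFC", "DLPFC", "SFG")
INPUTS = ("stim", "regular", "different")


def _load_space_spec() -> dict:
    with resources.files("precistim.data").joinpath("model_space.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class DCMModel:
    """One motif: node labels plus boolean connectivity masks.

    Masks use the convention ``mask[i, j]`` = connection from node j to
    node i.  ``D_masks`` maps a gating node's label to the mask of
    connections it gates; bilinear motifs have no gates.
    """

    name: str
    nodes: tuple[str, ...]
    A_mask: np.ndarray  # (n, n) bool, diagonal True (self-connections)
    B_masks: dict  # input name -> (n, n) bool
    C_mask: np.ndarray  # (n, m) bool
    D_masks: dict  # gating node name -> (n, n) bool

    @property
    def is_nonlinear(self) -> bool:
        return any(m.any() for m in self.D_masks.values())

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "nodes": list(self.nodes),
            "A_mask": self.A_mask.astype(int).tolist(),
            "B_masks": {k: v.astype(int).tolist() for k, v in self.B_masks.items()},
            "C_mask": self.C_mask.astype(int).tolist(),
            "D_masks": {k: v.astype(int).tolist() for k, v in self.D_masks.items()},
        }


@dataclass
class DCMParams:
    """Values for every allowed connection of a model (all in s^-1).

    ``A`` holds off-diagonal couplings only; effective self-connections are
    ``-0.5 * exp(theta_self_i)`` and live on the diagonal of
    :meth:`effective_A`.
    """

    A: np.ndarray  # (n, n), off-diagonal entries
    B: dict  # input name -> (n, n)
    C: np.ndarray  # (n, m)
    D: dict  # gating node -> (n, n)
    theta_self: np.ndarray  # (n,)

    def effective_A(self) -> np.ndarray:
        A = self.A.copy()
        np.fill_diagonal(A, -0.5 * np.exp(self.theta_self))
        return A


@dataclass(frozen=True)
class HemoParams:
    """Balloon-model constants (defaults are conventional literature values)."""

    kappa: float = 0.64  # signal decay, s^-1
    gamma: float = 0.32  # flow feedback, s^-1
    tau: float = 2.0  # mean transit time, s
    alpha: float = 0.32  # vessel stiffness exponent
    E0: float = 0.4  # resting oxygen extraction fraction
    V0: float = 0.04  # resting venous volume fraction

    def __post_init__(self) -> None:
        if min(self.kappa, self.gamma, self.tau, self.V0) <= 0:
            raise ValueError("hemodynamic rate/volume parameters must be > 0")
        if not (0 < self.E0 < 1):
            raise ValueError("E0 must be in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class InputSet:
    """Driving and modulatory input streams sampled on a common dt grid."""

    dt: float  # s
    u_stim: np.ndarray
    u_regular: np.ndarray
    u_different: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.u_stim)
        if not (len(self.u_regular) == n and len(self.u_different) == n):
            raise ValueError("input streams must share one length")
        for name in ("u_stim", "u_regular", "u_different"):
            u = np.asarray(getattr(self, name), dtype=float)
            if not np.isin(u, (0.0, 1.0)).all():
                raise ValueError(f"{name} must be a binary boxcar stream")
            setattr(self, name, u)

    @property
    def stacked(self) -> np.ndarray:
        """(T, 3) array in canonical input order (stim, regular, different)."""
        return np.column_stack([self.u_stim, self.u_regular, self.u_different])

    @property
    def duration(self) -> float:
        return len(self.u_stim) * self.dt

    def to_tsv(self, path) -> None:
        pd.DataFrame({
            "time_s": np.arange(len(self.u_stim)) * self.dt,
            "u_stim": self.u_stim,
            "u_regular": self.u_regular,
            "u_different": self.u_different,
        }).to_csv(path, sep="\t", index=False)


@dataclass
class BOLDSeries:
    """Region x time BOLD matrix with its sampling interval and provenance."""

    data: np.ndarray  # (n_regions, n_time)
    tr: float  # s
    nodes: tuple[str, ...] = NODES
    provenance: dict = field(default_factory=dict)

    @property
    def n_time(self) -> int:
        return self.data.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.data.T, columns=list(self.nodes))
        df.insert(0, "time_s", np.arange(self.n_time) * self.tr)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, tr: float | None = None) -> "BOLDSeries":
        df = pd.read_csv(path)
        t = df.pop("time_s").to_numpy()
        if tr is None:
            tr = float(t[1] - t[0]) if len(t) > 1 else 1.0
        return cls(data=df.to_numpy().T, tr=tr, nodes=tuple(df.columns))


def _edges_to_mask(edges, n, index) -> np.ndarray:
    mask = np.zeros((n, n), dtype=bool)
    for src, dst in edges:
        mask[index[dst], index[src]] = True
    return mask


def build_model_space() -> list[DCMModel]:
    """Construct the seven motifs (Diamond, Fork, Legs 1/2, Stork 1/2/3)."""
    spec = _load_space_spec()
    nodes = tuple(spec["nodes"])
    inputs = tuple(spec["inputs"])
    n, m = len(nodes), len(inputs)
    idx = {nm: i for i, nm in enumerate(nodes)}
    uidx = {nm: i for i, nm in enumerate(inputs)}
    common = spec["common"]
    models = []
    for name, extra in spec["models"].items():
        A = _edges_to_mask(common["a_edges"] + extra.get("a_edges", []), n, idx)
        np.fill_diagonal(A, True)
        B = {}
        for u in inputs:
            edges = (common["b_edges"].get(u, [])
                     + extra.get("b_edges", {}).get(u, []))
            if edges:
                B[u] = _edges_to_mask(edges, n, idx)
        C = np.zeros((n, m), dtype=bool)
        for u, targets in common["c_targets"].items():
            for t in targets:
                C[idx[t], uidx[u]] = True
        D = {}
        for gate in extra.get("d_edges", []):
            g = gate["gate"]
            if g not in D:
                D[g] = np.zeros((n, n), dtype=bool)
            src, dst = gate["edge"]
            D[g][idx[dst], idx[src]] = True
        models.append(DCMModel(name=name, nodes=nodes, A_mask=A,
                               B_masks=B, C_mask=C, D_masks=D))
    return models


def default_generating_params(model: DCMModel) -> DCMParams:
    """Group-mean generating parameters used by the synthetic study.

    The design mirrors the study's logic: the unconditional forward
    couplings from IPL are weak (0.1 s^-1) while the condition-specific
    modulations are strong (1.0 s^-1), so rPFC responds mainly on regular
    trials and DLPFC mainly on different trials; afferents to SFG are
    0.3 s^-1 with a weak negative DLPFC->IPL backward coupling, driving
    input 0.8, and gates of 1.5 s^-1 per unit state.  Under gating the SFG
    then expresses a regular-by-different product response that no purely
    bilinear motif reproduces — the interaction signature that makes the
    nonlinear motifs empirically distinguishable.
    """
    n = model.n_nodes
    idx = {nm: i for i, nm in enumerate(model.nodes)}
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j or not model.A_mask[i, j]:
                continue
            if (model.nodes[j], model.nodes[i]) == ("DLPFC", "IPL"):
                A[i, j] = -0.2  # backward connection
            elif model.nodes[j] == "IPL":
                A[i, j] = 0.1  # weak unconditional forward drive
            else:
                A[i, j] = 0.3  # afferents to SFG
    B = {u: np.where(mask, 1.0, 0.0) for u, mask in model.B_masks.items()}
    C = np.where(model.C_mask, 0.8, 0.0)
    D = {g: np.where(mask, 1.5, 0.0) for g, mask in model.D_masks.items()}
    return DCMParams(A=A, B=B, C=C, D=D, theta_self=np.zeros(n))


def neural_drift(x: np.ndarray, u: np.ndarray, params: DCMParams,
                 model: DCMModel) -> np.ndarray:
    """dx/dt = (A + sum_j u_j B^(j) + sum_k x_k D^(k)) x + C u."""
    n = model.n_nodes
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    if x.shape != (n,):
        raise ValueError(f"state must have shape ({n},), got {x.shape}")
    if u.shape != (len(INPUTS),):
        raise ValueError(f"inputs must have shape ({len(INPUTS)},), got {u.shape}")
    M = params.effective_A() * model.A_mask
    for j, name in enumerate(INPUTS):
        if name in model.B_masks:
            M = M + u[j] * params.B[name] * model.B_masks[name]
    for k, gate in enumerate(model.nodes):
        if gate in model.D_masks:
            M = M + x[k] * params.D[gate] * model.D_masks[gate]
    return M @ x + (np.where(model.C_mask, params.C, 0.0) @ u)


def hemodynamics_step(h: np.ndarray, x: float, p: HemoParams
                      ) -> tuple[np.ndarray, float]:
    """One region's balloon-model derivative and current BOLD value.

    ``h = (s, f, v, q)``: vasodilatory signal, inflow, venous volume,
    deoxyhemoglobin.  Derivatives:

        ds/dt = x - kappa s - gamma (f - 1)
        df/dt = s
        tau dv/dt = f - v^(1/alpha)
        tau dq/dt = f (1 - (1-E0)^(1/f)) / E0 - v^(1/alpha) q / v

    BOLD = V0 (k1 (1-q) + k2 (1 - q/v) + k3 (1-v)) with k1 = 7 E0, k2 = 2,
    k3 = 2 E0 - 0.2.
    """
    s, f, v, q = np.asarray(h, dtype=float)
    if v <= 0 or q <= 0:
        raise ValueError("volume and deoxyhemoglobin states must stay positive")
    ds = x - p.kappa * s - p.gamma * (f - 1.0)
    df = s
    fv = v ** (1.0 / p.alpha)
    dv = (f - fv) / p.tau
    dq = (f * (1.0 - (1.0 - p.E0) ** (1.0 / f)) / p.E0 - fv * q / v) / p.tau
    return np.array([ds, df, dv, dq]), bold_signal(v, q, p)


def bold_signal(v, q, p: HemoParams):
    k1, k2, k3 = 7.0 * p.E0, 2.0, 2.0 * p.E0 - 0.2
    return p.V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))


def pack_arrays(model: DCMModel, params: DCMParams
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Dense (A, B, C, D) arrays for the integrator; masked entries zeroed."""
    n, m = model.n_nodes, len(INPUTS)
    A = params.effective_A() * model.A_mask
    np.fill_diagonal(A, -0.5 * np.exp(params.theta_self))
    B = np.zeros((m, n, n))
    for j, name in enumerate(INPUTS):
        if name in model.B_masks:
            B[j] = params.B[name] * model.B_masks[name]
    C = np.where(model.C_mask, params.C, 0.0)
    D = np.zeros((n, n, n))
    for k, gate in enumerate(model.nodes):
        if gate in model.D_masks:
            D[k] = params.D[gate] * model.D_masks[gate]
    return A, B, C, D


class SimulationError(RuntimeError):
    pass


def simulate_bold(model: DCMModel, params: DCMParams, hemo: HemoParams,
                  inputs: InputSet, tr: float = 2.0, noise_sd: float = 0.0,
                  seed: int | None = None, ar_coef: float = 0.0,
                  x_bound: float = 1e3) -> BOLDSeries:
    """Integrate the DCM with fixed-step RK4 and sample BOLD every TR.

    Observation noise is additive Gaussian with SD ``noise_sd``; setting
    ``ar_coef`` in (0, 1) makes it AR(1) with that lag-1 coefficient at
    matched marginal variance.  Raises :class:`SimulationError` naming the
    failure time if the neural state diverges or a hemodynamic state leaves
    its positive domain.
    """
    check = stability_check(params, model)
    if not check["stable"]:
        raise SimulationError(
            f"model {model.name} unstable at rest (margin {check['margin']:.3f})")
    A, B, C, D = pack_arrays(model, params)
    u = inputs.stacked
    n_time = int(np.floor(inputs.duration / tr))
    sample_idx = np.round(np.arange(n_time) * tr / inputs.dt).astype(np.int64)
    bold, fail = integrate_batch(
        A[None], B[None], C[None], D[None], u, inputs.dt, sample_idx,
        hemo.kappa, hemo.gamma, np.array([hemo.tau]), hemo.alpha,
        hemo.E0, hemo.V0, x_bound)
    if fail[0] >= 0:
        raise SimulationError(
            f"state blow-up at t = {fail[0] * inputs.dt:.2f} s "
            f"(model {model.name})")
    y = bold[0].T  # (n_regions, n_time)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eps = rng.normal(0.0, noise_sd, size=y.shape)
        if ar_coef:
            innov_sd = np.sqrt(1.0 - ar_coef**2)
            for t in range(1, y.shape[1]):
                eps[:, t] = ar_coef * eps[:, t - 1] + innov_sd * eps[:, t]
        y = y + eps
    return BOLDSeries(data=y, tr=tr, nodes=model.nodes,
                      provenance={"model": model.name, "seed": seed,
                                  "noise_sd": noise_sd, "dt": inputs.dt})


def stability_check(params: DCMParams, model: DCMModel) -> dict:
    """Eigenvalue check of the rest-point Jacobian (= A; gates vanish at x=0)."""
    A = params.effective_A() * model.A_mask
    np.fill_diagonal(A, -0.5 * np.exp(params.theta_self))
    eig = np.linalg.eigvals(A)
    margin = -float(eig.real.max())
    return {"stable": margin > 0, "margin": margin, "eigenvalues": eig}
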