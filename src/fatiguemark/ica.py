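"""Eye-movement artifact removal by independent component analysis.

The full session is decomposed into as many FastICA components as there
are channels; any component whose time course has an absolute Pearson
correlation above a threshold (default 0.1) with the raw frontal
reference channels (LFL and RFL) is treated as ocular and dropped before
back-projection.  |r| is used because ICA component signs are arbitrary.
Ocular potentials are picked up by both lateral frontal electrodes, so
the default rule requires the threshold to be exceeded against *both*
references; ``reference_mode="any"`` switches to the looser
either-reference rule.

This is a session-level preprocessing stage: correlations are computed
against the raw frontal traces over the entire recording, and epoching
happens afterwards.  Cleaning is not idempotent — re-running ICA on a
cleaned session may find a different decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA

from .core import SessionRecording


class ICAConvergenceError(RuntimeError):
    def __init__(self, n_iter: int, max_iter: int):
        super().__init__(
            f"FastICA did not converge within {max_iter} iterations "
            f"(ran {n_iter})"
        )
        self.n_iter = n_iter


@dataclass
class ICACleanReport:
    """Audit record of one cleaning pass."""

    n_components: int
    threshold: float
    #: per-component Pearson correlations with the raw reference channels
    r_lfl: np.ndarray = field(repr=False)
    r_rfl: np.ndarray = field(repr=False)
    removed_component_indices: tuple[int, ...] = ()
    reference_mode: str = "both"

    def criterion(self, i: int) -> float:
        """The statistic compared against the threshold for component i."""
        a, b = abs(self.r_lfl[i]), abs(self.r_rfl[i])
        return min(a, b) if self.reference_mode == "both" else max(a, b)

    def __post_init__(self) -> None:
        if self.reference_mode not in ("both", "any"):
            raise ValueError("reference_mode must be 'both' or 'any'")
        r = np.concatenate([np.abs(self.r_lfl), np.abs(self.r_rfl)])
        if np.any(r > 1 + 1e-9):
            raise ValueError("correlations must satisfy |r| <= 1")
        expected = tuple(
            int(i)
            for i in range(self.n_components)
            if self.criterion(i) > self.threshold
        )
        if tuple(self.removed_component_indices) != expected:
            raise ValueError(
                "removed indices do not match the correlation criterion"
            )

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "threshold": self.threshold,
            "reference_mode": self.reference_mode,
            "r_lfl": [float(v) for v in self.r_lfl],
            "r_rfl": [float(v) for v in self.r_rfl],
            "removed_component_indices": list(self.removed_component_indices),
        }


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom <= 0:
        return 0.0
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def remove_eye_components(
    session: SessionRecording,
    threshold: float = 0.1,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-3,
    fun: str = "cube",
    fit_stride: int = 1,
    reference_mode: str = "both",
) -> tuple[SessionRecording, ICACleanReport]:
    """Decompose, drop frontal-correlated components, and back-project.

    ``fit_stride`` > 1 estimates the unmixing matrix on every k-th sample
    (the component time courses and back-projection still use the full
    recording), which makes long sessions tractable without changing the
    session length.  With ``threshold=1.0`` nothing can be removed and the
    reconstruction equals the input up to numerical round-off.

    Returns the cleaned session (same shape, rate and channel order) and
    an :class:`ICACleanReport` listing per-component correlations.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if fit_stride < 1:
        raise ValueError("fit_stride must be >= 1")
    X = session.data.T  # samples x channels
    n_comp = session.channels.n_channels
    ica = FastICA(
        n_components=n_comp,
        whiten="unit-variance",
        random_state=seed,
        max_iter=max_iter,
        tol=tol,
        fun=fun,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            ica.fit(X[::fit_stride])
        except UserWarning as w:  # sklearn warns instead of raising
            if "did not converge" in str(w):
                raise ICAConvergenceError(max_iter, max_iter) from None
            raise
    if ica.n_iter_ >= max_iter:
        raise ICAConvergenceError(ica.n_iter_, max_iter)

    sources = ica.transform(X)  # samples x components, full session
    lfl = session.channel("LFL")
    rfl = session.channel("RFL")
    r_lfl = np.array([_pearson(sources[:, i], lfl) for i in range(n_comp)])
    r_rfl = np.array([_pearson(sources[:, i], rfl) for i in range(n_comp)])
    if reference_mode == "both":
        crit = np.minimum(np.abs(r_lfl), np.abs(r_rfl))
    elif reference_mode == "any":
        crit = np.maximum(np.abs(r_lfl), np.abs(r_rfl))
    else:
        raise ValueError("reference_mode must be 'both' or 'any'")
    removed = tuple(int(i) for i in range(n_comp) if crit[i] > threshold)

    kept = sources.copy()
    kept[:, list(removed)] = 0.0
    cleaned = kept @ ica.mixing_.T + ica.mean_
    out = SessionRecording(
        data=cleaned.T,
        fs=session.fs,
        channels=session.channels,
        session_id=session.session_id,
    )
    report = ICACleanReport(
        n_components=n_comp,
        threshold=threshold,
        r_lfl=r_lfl,
        r_rfl=r_rfl,
        removed_component_indices=removed,
        reference_mode=reference_mode,
    )
    return out, report
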