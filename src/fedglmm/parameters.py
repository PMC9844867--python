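"""Parameter layout and the packed parameter vector.

The full parameter vector is theta = (beta, delta_1, ..., delta_K), where
beta holds the fixed effects common to every site and delta_k = (alpha_k,
gamma_k) holds the k-th site's site-specific fixed effects and variance
components.  Under homogeneity flags the alpha and/or gamma blocks are shared
and appear exactly once, directly after beta.

Variance components are stored on the log scale (eta = log gamma), so every
outer optimization and Newton step is unconstrained; the bijection back to
the covariance matrix is B(gamma) = diag(exp(eta)) per grouping factor.  For
the identity link the residual variance is the last element of the gamma
block.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np


class ParamLayout:
    """Index bookkeeping for theta = (beta, delta_1, ..., delta_K).

    Blocks are laid out as: ``beta``, then shared ``alpha``/``gamma`` blocks
    (if the model is homogeneous in them), then per-site ``alpha[sid]``,
    ``gamma[sid]`` blocks in the order the site ids were given.
    """

    def __init__(self, spec, site_ids):
        self.spec = spec
        self.site_ids = [str(s) for s in site_ids]
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("duplicate site ids in layout")

        self.blocks: dict[str, slice] = {}
        self.labels: list[str] = []

        def add(name: str, labs: list[str]) -> None:
            start = len(self.labels)
            self.labels.extend(labs)
            self.blocks[name] = slice(start, len(self.labels))

        gamma_labs = list(spec.gamma_labels())
        add("beta", [f"beta:{c}" for c in spec.common])
        if spec.alpha_shared and spec.site_specific:
            add("alpha", [f"alpha:{c}" for c in spec.site_specific])
        if spec.gamma_shared:
            add("gamma", [f"gamma:{g}" for g in gamma_labs])
        for sid in self.site_ids:
            if not spec.alpha_shared and spec.site_specific:
                add(f"alpha[{sid}]", [f"alpha[{sid}]:{c}" for c in spec.site_specific])
            if not spec.gamma_shared:
                add(f"gamma[{sid}]", [f"gamma[{sid}]:{g}" for g in gamma_labs])

        self.p = len(self.labels)
        self.p_beta = len(spec.common)
        self.p_alpha = len(spec.site_specific)
        self.p_gamma = len(gamma_labs)

        shared: list[np.ndarray] = [self._block_idx("beta")]
        if "alpha" in self.blocks:
            shared.append(self._block_idx("alpha"))
        if "gamma" in self.blocks:
            shared.append(self._block_idx("gamma"))
        #: indices of the blocks shared across sites (the "hub" of the arrow
        #: structure of the global Hessian)
        self.shared_idx = np.concatenate(shared)

        #: per-site indices of the site-exclusive blocks (arrow "spikes")
        self.site_block_idx: dict[str, np.ndarray] = {}
        #: per-site map from the site-local vector (beta, alpha, gamma) to
        #: global theta indices
        self.site_map: dict[str, np.ndarray] = {}
        for sid in self.site_ids:
            own: list[np.ndarray] = []
            parts = [self._block_idx("beta")]
            if spec.site_specific:
                key = "alpha" if spec.alpha_shared else f"alpha[{sid}]"
                parts.append(self._block_idx(key))
                if not spec.alpha_shared:
                    own.append(self._block_idx(key))
            key = "gamma" if spec.gamma_shared else f"gamma[{sid}]"
            parts.append(self._block_idx(key))
            if not spec.gamma_shared:
                own.append(self._block_idx(key))
            self.site_map[sid] = np.concatenate(parts)
            self.site_block_idx[sid] = (
                np.concatenate(own) if own else np.empty(0, dtype=int)
            )

    def _block_idx(self, name: str) -> np.ndarray:
        s = self.blocks[name]
        return np.arange(s.start, s.stop)

    @property
    def p_local(self) -> int:
        return self.p_beta + self.p_alpha + self.p_gamma

    def local_labels(self, sid: str | None = None) -> list[str]:
        spec = self.spec
        labs = [f"beta:{c}" for c in spec.common]
        labs += [f"alpha:{c}" for c in spec.site_specific]
        labs += [f"gamma:{g}" for g in spec.gamma_labels()]
        return labs

    def zeros(self) -> np.ndarray:
        return np.zeros(self.p)


@dataclass
class Theta:
    """A concrete value of the full parameter vector with its layout."""

    layout: ParamLayout
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.layout.p,):
            raise ValueError(
                f"theta has length {self.values.size}, layout expects {self.layout.p}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("theta contains non-finite values")

    def block(self, name: str) -> np.ndarray:
        return self.values[self.layout.blocks[name]]

    @property
    def beta(self) -> np.ndarray:
        return self.block("beta")

    def site_vector(self, sid: str) -> np.ndarray:
        """The site-local vector (beta, alpha_k, gamma_k) for one site."""
        return self.values[self.layout.site_map[str(sid)]]

    def replace(self, values: np.ndarray) -> "Theta":
        return Theta(self.layout, np.asarray(values, dtype=float).copy())

    def site_digest(self, sid: str) -> str:
        """SHA-256 of a canonical decimal rendering of the components a site
        evaluates at; used to detect protocol drift across manual transfers."""
        canon = ",".join(repr(float(v)) for v in self.site_vector(sid))
        return hashlib.sha256(canon.encode("ascii")).hexdigest()

    def copy(self) -> "Theta":
        return Theta(self.layout, self.values.copy())
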