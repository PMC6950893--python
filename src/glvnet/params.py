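"""Model coefficients and per-coefficient sign restrictions."""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

#: allowed sign symbols for a single coefficient
SIGNS = ("positive", "negative", "zero", "free")

_SIGN_BOUNDS = {
    "positive": (0.0, np.inf),
    "negative": (-np.inf, 0.0),
    "zero": (0.0, 0.0),
    "free": (-np.inf, np.inf),
}


@dataclass(frozen=True)
class GLVParameters:
    """Coefficients of a generalized Lotka-Volterra community model.

    ``alpha`` holds per-capita net growth rates (1/time), ``beta`` the pairwise
    interaction matrix (row i, column j = effect of species j on species i, in
    1/(abundance*time)), and ``epsilon`` the optional per-species susceptibility
    to an exogenous species.
    """

    alpha: np.ndarray
    beta: np.ndarray
    epsilon: np.ndarray | None = None
    species_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        n = alpha.size
        if alpha.ndim != 1:
            raise ValueError("alpha must be a vector")
        if beta.shape != (n, n):
            raise ValueError(f"beta must be {n}x{n}, got {beta.shape}")
        if not (np.all(np.isfinite(alpha)) and np.all(np.isfinite(beta))):
            raise ValueError("coefficients must be finite")
        eps = self.epsilon
        if eps is not None:
            eps = np.asarray(eps, dtype=float)
            if eps.shape != (n,):
                raise ValueError(f"epsilon must have length {n}, got {eps.shape}")
            if not np.all(np.isfinite(eps)):
                raise ValueError("epsilon must be finite")
        ids = self.species_ids
        if ids is not None:
            ids = tuple(str(s) for s in ids)
            if len(ids) != n:
                raise ValueError("species_ids length must match alpha")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "epsilon", eps)
        object.__setattr__(self, "species_ids", ids)

    @property
    def n_species(self) -> int:
        return self.alpha.size

    def with_epsilon(self, epsilon: np.ndarray | None) -> "GLVParameters":
        return replace(self, epsilon=epsilon)

    def interior_fixed_point(self) -> np.ndarray:
        """Solve alpha + beta @ x = 0 for the coexistence equilibrium."""
        return np.linalg.solve(self.beta, -self.alpha)

    # -- JSON round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        out = {
            "alpha": self.alpha.tolist(),
            "beta": self.beta.ravel().tolist(),  # row-major
            "n_species": self.n_species,
        }
        if self.epsilon is not None:
            out["epsilon"] = self.epsilon.tolist()
        if self.species_ids is not None:
            out["species_ids"] = list(self.species_ids)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "GLVParameters":
        n = int(data["n_species"])
        return cls(
            alpha=np.asarray(data["alpha"], dtype=float),
            beta=np.asarray(data["beta"], dtype=float).reshape(n, n),
            epsilon=(np.asarray(data["epsilon"], dtype=float) if "epsilon" in data else None),
            species_ids=tuple(data["species_ids"]) if "species_ids" in data else None,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GLVParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class SignConstraintSet:
    """Sign restrictions on gLV coefficients derived from a summary food web.

    ``alpha_sign[i]`` restricts the growth rate of species i and
    ``beta_sign[i, j]`` the effect of species j on species i; values are drawn
    from ``{"positive", "negative", "zero", "free"}``.  ``epsilon_sign``
    optionally restricts susceptibilities to an exogenous species.
    """

    alpha_sign: np.ndarray
    beta_sign: np.ndarray
    epsilon_sign: np.ndarray | None = None
    species_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        alpha_sign = np.asarray(self.alpha_sign, dtype=object)
        beta_sign = np.asarray(self.beta_sign, dtype=object)
        n = alpha_sign.size
        if beta_sign.shape != (n, n):
            raise ValueError(f"beta_sign must be {n}x{n}, got {beta_sign.shape}")
        for arr in (alpha_sign.ravel(), beta_sign.ravel()):
            bad = sorted({s for s in arr if s not in SIGNS})
            if bad:
                raise ValueError(f"unknown sign symbols {bad}; allowed: {SIGNS}")
        eps = self.epsilon_sign
        if eps is not None:
            eps = np.asarray(eps, dtype=object)
            if eps.shape != (n,):
                raise ValueError("epsilon_sign length mismatch")
        object.__setattr__(self, "alpha_sign", alpha_sign)
        object.__setattr__(self, "beta_sign", beta_sign)
        object.__setattr__(self, "epsilon_sign", eps)
        if self.species_ids is not None:
            object.__setattr__(self, "species_ids", tuple(str(s) for s in self.species_ids))

    @property
    def n_species(self) -> int:
        return self.alpha_sign.size

    @classmethod
    def unconstrained(cls, n: int, species_ids=None) -> "SignConstraintSet":
        return cls(
            alpha_sign=np.full(n, "free", dtype=object),
            beta_sign=np.full((n, n), "free", dtype=object),
            species_ids=tuple(species_ids) if species_ids is not None else None,
        )

    @classmethod
    def from_signs(
        cls, alpha: np.ndarray, beta: np.ndarray, epsilon: np.ndarray | None = None,
        species_ids=None,
    ) -> "SignConstraintSet":
        """Constraints matching the sign pattern of numeric coefficients.

        Zero entries are pinned to zero; nonzero entries keep their sign.
        """
        def conv(v):
            return "zero" if v == 0 else ("positive" if v > 0 else "negative")

        alpha = np.asarray(alpha, dtype=float)
        beta = np.asarray(beta, dtype=float)
        return cls(
            alpha_sign=np.vectorize(conv, otypes=[object])(alpha),
            beta_sign=np.vectorize(conv, otypes=[object])(beta),
            epsilon_sign=(np.vectorize(conv, otypes=[object])(np.asarray(epsilon, dtype=float))
                          if epsilon is not None else None),
            species_ids=tuple(species_ids) if species_ids is not None else None,
        )

    def bounds_row(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Box bounds for species i's regression vector [alpha_i, beta_i1..beta_iN]."""
        signs = [self.alpha_sign[i]] + list(self.beta_sign[i])
        lo = np.array([_SIGN_BOUNDS[s][0] for s in signs])
        hi = np.array([_SIGN_BOUNDS[s][1] for s in signs])
        return lo, hi

    def epsilon_bounds(self, i: int) -> tuple[float, float]:
        if self.epsilon_sign is None:
            return (-np.inf, np.inf)
        return _SIGN_BOUNDS[self.epsilon_sign[i]]

    def is_satisfied_by(self, params: GLVParameters, atol: float = 0.0) -> bool:
        """Check that numeric coefficients respect every sign restriction."""
        def ok(value, sign):
            lo, hi = _SIGN_BOUNDS[sign]
            return (lo - atol) <= value <= (hi + atol)

        if not all(ok(params.alpha[i], self.alpha_sign[i]) for i in range(self.n_species)):
            return False
        n = self.n_species
        if not all(ok(params.beta[i, j], self.beta_sign[i, j]) for i in range(n) for j in range(n)):
            return False
        if self.epsilon_sign is not None and params.epsilon is not None:
            if not all(ok(params.epsilon[i], self.epsilon_sign[i]) for i in range(n)):
                return False
        return True

    def n_free_parameters(self, include_epsilon: bool = False) -> int:
        """Number of coefficients not pinned to zero."""
        count = int(np.sum(self.alpha_sign != "zero"))
        count += int(np.sum(self.beta_sign != "zero"))
        if include_epsilon and self.epsilon_sign is not None:
            count += int(np.sum(self.epsilon_sign != "zero"))
        return count

    # -- symbol-table I/O ---------------------------------------------------
    _SYMBOL = {"positive": "+", "negative": "-", "zero": "0", "free": "?"}
    _FROM_SYMBOL = {"+": "positive", "-": "negative", "0": "zero", "?": "free"}

    def to_symbol_table(self) -> "pd.DataFrame":
        """Signed-symbol matrix: rows affected species, columns affecting
        species, last column the growth-rate sign."""
        import pandas as pd

        ids = self.species_ids or tuple(f"sp{i+1}" for i in range(self.n_species))
        data = np.empty((self.n_species, self.n_species + 1), dtype=object)
        for i in range(self.n_species):
            for j in range(self.n_species):
                data[i, j] = self._SYMBOL[self.beta_sign[i, j]]
            data[i, -1] = self._SYMBOL[self.alpha_sign[i]]
        return pd.DataFrame(data, index=list(ids), columns=list(ids) + ["growth"])

    @classmethod
    def from_symbol_table(cls, frame: "pd.DataFrame") -> "SignConstraintSet":
        ids = tuple(str(i) for i in frame.index)
        n = len(ids)
        beta_sign = np.empty((n, n), dtype=object)
        alpha_sign = np.empty(n, dtype=object)
        for i in range(n):
            for j in range(n):
                beta_sign[i, j] = cls._FROM_SYMBOL[str(frame.iloc[i, j]).strip()]
            alpha_sign[i] = cls._FROM_SYMBOL[str(frame.iloc[i, n]).strip()]
        return cls(alpha_sign=alpha_sign, beta_sign=beta_sign, species_ids=ids)
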