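"""Minimal estimator base providing the fit/get_params/set_params protocol.

Estimators in this package follow the scikit-learn contract (keyword-only
constructor parameters stored verbatim, fitted attributes with a trailing
underscore, ``get_params``/``set_params`` for pipeline and grid-search
composition) without depending on scikit-learn itself.
"""

from __future__ import annotations

import inspect
from typing import Any


class BaseEstimator:
    """Duck-typed scikit-learn estimator base.

    Subclasses must accept all configuration in ``__init__`` keyword
    arguments and store each argument unmodified on an attribute of the
    same name.
    """

    @classmethod
    def _param_names(cls) -> list[str]:
        sig = inspect.signature(cls.__init__)
        return [
            name
            for name, p in sig.parameters.items()
            if name != "self" and p.kind not in (p.VAR_POSITIONAL, p.VAR_KEYWORD)
        ]

    def get_params(self, deep: bool = True) -> dict[str, Any]:
        return {name: getattr(self, name) for name in self._param_names()}

    def set_params(self, **params: Any) -> "BaseEstimator":
        valid = set(self._param_names())
        for key, value in params.items():
            if key not in valid:
                raise ValueError(
                    f"Invalid parameter {key!r} for estimator "
                    f"{type(self).__name__}. Valid parameters: {sorted(valid)}"
                )
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        params = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({params})"

    def _check_is_fitted(self, attr: str) -> None:
        if not hasattr(self, attr):
            raise RuntimeError(
                f"This {type(self).__name__} instance is not fitted yet; "
                "call 'fit' before using this method."
            )
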