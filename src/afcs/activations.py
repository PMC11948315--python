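"""Catalog of candidate activation functions and weight-preserving swapping.

The controller in :mod:`afcs.controller` treats the activation function of a
network as a schedulable hyperparameter: training may switch from one scalar
nonlinearity to another mid-run without touching any learnable parameter.
This module defines the candidate functions (closed form and derivative),
an ordered catalog — order is the tie-breaking key when probe losses tie —
and :func:`swap_activation`, which rebinds every registered activation site
of a model to a new function while leaving the weights bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Protocol, runtime_checkable

import numpy as np
from scipy.special import erf, expit

__all__ = [
    "ActivationSpec",
    "ActivationCatalog",
    "ActivationSite",
    "CatalogError",
    "StructuralError",
    "DEFAULT_CATALOG",
    "DEFAULT_LIST_AF",
    "activation_value",
    "swap_activation",
]

# canonical self-normalizing constants (Klambauer et al. scaled ELU)
SELU_LAMBDA = 1.0507009873554804934193349852946
SELU_ALPHA = 1.6732632423543772848170429916717

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


class CatalogError(KeyError):
    """An activation name is not present in the catalog."""


class StructuralError(ValueError):
    """A model does not expose any swappable activation sites."""


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(x):
    return (x > 0).astype(float)


def _tanh_grad(x):
    t = np.tanh(x)
    return 1.0 - t * t


def _elu(x, alpha=1.0):
    return np.where(x >= 0, x, alpha * np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x, alpha=1.0):
    return np.where(x >= 0, 1.0, alpha * np.exp(np.minimum(x, 0.0)))


def _selu(x):
    return SELU_LAMBDA * _elu(x, SELU_ALPHA)


def _selu_grad(x):
    return SELU_LAMBDA * _elu_grad(x, SELU_ALPHA)


def _silu(x):
    return x * expit(x)


def _silu_grad(x):
    s = expit(x)
    return s * (1.0 + x * (1.0 - s))


def _softplus(x):
    return np.logaddexp(0.0, x)


def _mish(x):
    return x * np.tanh(_softplus(x))


def _mish_grad(x):
    t = np.tanh(_softplus(x))
    return t + x * (1.0 - t * t) * expit(x)


def _gelu(x):
    # exact-erf form, not the tanh approximation
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x):
    phi = np.exp(-0.5 * x * x) * _INV_SQRT_2PI
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * phi


@dataclass(frozen=True)
class ActivationSpec:
    """A named scalar nonlinearity with closed-form value and derivative.

    ``fn`` and ``grad`` are vectorized maps R -> R, total on finite input.
    ``parameters`` records any named constants (e.g. the ELU alpha).
    """

    name: str
    fn: Callable[[np.ndarray], np.ndarray]
    grad: Callable[[np.ndarray], np.ndarray]
    parameters: Mapping[str, float] = field(default_factory=dict)

    def __call__(self, x):
        return self.fn(np.asarray(x, dtype=float))


class ActivationCatalog:
    """An ordered, duplicate-free collection of :class:`ActivationSpec`.

    Insertion order is significant: ties in probe-loss rankings are broken
    by catalog/candidate order, so two catalogs with the same members but
    different order are different objects.
    """

    def __init__(self, specs: Iterable[ActivationSpec] = ()):
        self._specs: dict[str, ActivationSpec] = {}
        for spec in specs:
            self.add(spec)

    def add(self, spec: ActivationSpec) -> None:
        if spec.name in self._specs:
            raise ValueError(f"duplicate activation name: {spec.name!r}")
        self._specs[spec.name] = spec

    def __getitem__(self, name: str) -> ActivationSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise CatalogError(
                f"unknown activation {name!r}; catalog has {list(self._specs)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __iter__(self) -> Iterator[str]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def subset(self, names: Iterable[str]) -> "ActivationCatalog":
        return ActivationCatalog(self[name] for name in names)

    # -- plain-text round trip (order-significant list of names) ------------
    def to_config(self) -> list[str]:
        return self.names

    @classmethod
    def from_config(
        cls, names: Iterable[str], base: "ActivationCatalog | None" = None
    ) -> "ActivationCatalog":
        base = DEFAULT_CATALOG if base is None else base
        return cls(base[name] for name in names)


DEFAULT_CATALOG = ActivationCatalog(
    [
        ActivationSpec("ReLU", _relu, _relu_grad),
        ActivationSpec("ELU", _elu, _elu_grad, {"alpha": 1.0}),
        ActivationSpec(
            "SELU", _selu, _selu_grad, {"lambda": SELU_LAMBDA, "alpha": SELU_ALPHA}
        ),
        ActivationSpec("Mish", _mish, _mish_grad),
        ActivationSpec("SiLU", _silu, _silu_grad),
        ActivationSpec("GELU", _gelu, _gelu_grad),
        ActivationSpec("Tanh", np.tanh, _tanh_grad),
    ]
)

#: Default candidate list for the switching controller.  Tanh is in the
#: catalog but not in the default list: on the reference trainings it either
#: failed to learn or produced the worst losses, so it was dropped.
DEFAULT_LIST_AF = ["ReLU", "ELU", "SELU", "Mish", "SiLU", "GELU"]


def activation_value(
    name: str, x: float, catalog: ActivationCatalog | None = None
) -> float:
    """Evaluate the named activation at a finite scalar ``x``."""
    catalog = DEFAULT_CATALOG if catalog is None else catalog
    return float(catalog[name](x))


@dataclass
class ActivationSite:
    """One swappable activation position inside a model.

    Models declare their sites at construction; swapping rebinds ``spec`` in
    place and is O(sites).  The classification head's softmax is never a
    site.
    """

    label: str
    spec: ActivationSpec

    @property
    def name(self) -> str:
        return self.spec.name

    def forward(self, x):
        return self.spec.fn(x)

    def backward(self, x):
        return self.spec.grad(x)


@runtime_checkable
class SupportsActivationSwap(Protocol):
    activation_sites: list[ActivationSite]


def swap_activation(
    model: SupportsActivationSwap,
    name: str,
    catalog: ActivationCatalog | None = None,
):
    """Make every registered activation site of ``model`` compute ``name``.

    Learnable parameters are untouched; swapping to the already-active
    function is a no-op.  Returns the (mutated) model.

    Raises
    ------
    CatalogError
        if ``name`` is not in the catalog.
    StructuralError
        if the model declares no swappable sites.
    """
    catalog = DEFAULT_CATALOG if catalog is None else catalog
    spec = catalog[name]
    sites = getattr(model, "activation_sites", None)
    if not sites:
        raise StructuralError(
            f"{type(model).__name__} declares no swappable activation sites"
        )
    for site in sites:
        site.spec = spec
    return model
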