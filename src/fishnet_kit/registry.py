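"""Method registry: string IDs -> selection functions and estimator classes."""

from __future__ import annotations

from functools import partial
from typing import Callable

from .baseline import HypergeomEnrichment, KSEnrichment, gsea_test, he_test
from .data_io import ValidationError
from .fishnet import FishNet, fishnet_test
from .rbna import FSNet, PFSNet, QPSP, SNet, pfsnet_test, qpsp_test, snet_family_test

METHODS: dict[str, Callable] = {
    "he": he_test,
    "gsea": gsea_test,
    "qpsp": qpsp_test,
    "snet": partial(snet_family_test, variant="snet"),
    "fsnet": partial(snet_family_test, variant="fsnet"),
    "pfsnet": pfsnet_test,
    "ffishnet": partial(fishnet_test, fuzzy=True),
    "fishnet": partial(fishnet_test, fuzzy=False),
}

ESTIMATORS = {
    "he": HypergeomEnrichment,
    "gsea": KSEnrichment,
    "qpsp": QPSP,
    "snet": SNet,
    "fsnet": FSNet,
    "pfsnet": PFSNet,
    "ffishnet": FishNet,
    "fishnet": partial(FishNet, fuzzy=False),
}


def resolve_method(method: str | Callable, **params) -> Callable:
    """Return ``f(matrix, classes, complexes) -> results`` for a method ID.

    A callable is passed through (with ``params`` bound if given).
    """
    if callable(method):
        return partial(method, **params) if params else method
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    f = METHODS[method]
    return partial(f, **params) if params else f
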