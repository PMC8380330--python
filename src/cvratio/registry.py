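"""Parameter registry: the blood screen's 25 parameters and their VT terms."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, Iterator, Optional, Union

import yaml

from .model import ParameterDef


class ParameterRegistry:
    """Ordered, key-unique collection of :class:`ParameterDef`."""

    def __init__(self, parameters: list[ParameterDef]):
        self._by_key: Dict[str, ParameterDef] = {}
        for p in parameters:
            if p.key in self._by_key:
                raise ValueError(f"duplicate parameter key: {p.key!r}")
            self._by_key[p.key] = p

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[ParameterDef]:
        return iter(self._by_key.values())

    def __contains__(self, key: str) -> bool:
        return key in self._by_key

    def __getitem__(self, key: str) -> ParameterDef:
        return self._by_key[key]

    def get(self, key: str) -> Optional[ParameterDef]:
        return self._by_key.get(key)

    @property
    def keys(self) -> list[str]:
        return list(self._by_key)


def load_registry(path: Union[str, Path, None] = None) -> ParameterRegistry:
    """Load a parameter registry from YAML.

    With no ``path``, the bundled registry is used: the 25 directly measured
    clinical-chemical and hematological parameters, 24 of which carry a VT
    ontology term (mean corpuscular volume has none).
    """
    if path is None:
        text = (
            resources.files("cvratio").joinpath("data/parameters.yaml").read_text("utf-8")
        )
    else:
        text = Path(path).read_text("utf-8")
    doc = yaml.safe_load(text)
    try:
        entries = doc["parameters"]
    except (TypeError, KeyError) as exc:
        raise ValueError("registry YAML must contain a 'parameters' list") from exc
    defs = [
        ParameterDef(
            key=e["key"],
            display_name=e.get("display_name", e["key"]),
            vt_term=e.get("vt_term"),
        )
        for e in entries
    ]
    return ParameterRegistry(defs)


def default_registry() -> ParameterRegistry:
    """The bundled 25-parameter blood-screen registry."""
    return load_registry(None)
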