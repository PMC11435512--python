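"""Prompt bank: per-class free-text descriptions used to build classifier
weights.

The bank holds exactly M descriptions per class (default M=10).  They
normally come from a captioner backend answering the fixed query
template about each representative image of the class; a deterministic
mock captioner keeps the whole pipeline offline-testable, and banks can
also be supplied directly as JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol

import numpy as np

__all__ = [
    "QUERY_TEMPLATE",
    "PromptBank",
    "Captioner",
    "build_query",
    "generate_prompts",
    "save_prompt_bank",
    "load_prompt_bank",
]

QUERY_TEMPLATE = "Can you help me describe this {cls} leaf?"

DEFAULT_M = 10


class Captioner(Protocol):
    name: str

    def describe(self, image: np.ndarray, query: str) -> str: ...


def build_query(class_name: str) -> str:
    """The per-class captioner query, with the class name substituted
    verbatim into the fixed template."""
    if not class_name or not class_name.strip():
        raise ValueError("class name must be non-empty")
    return QUERY_TEMPLATE.format(cls=class_name)


@dataclass
class PromptBank:
    """Ordered per-class prompt strings plus provenance tags."""

    class_names: list[str]
    prompts: dict[str, list[str]]
    provenance: dict[str, list[str]] = field(default_factory=dict)
    M: int | None = None

    def __post_init__(self) -> None:
        if not self.class_names:
            raise ValueError("prompt bank needs at least one class")
        for name in self.class_names:
            if name not in self.prompts:
                raise ValueError(f"class {name!r} has no prompt list")
            cleaned = [p.strip() for p in self.prompts[name]]
            if not cleaned or any(not p for p in cleaned):
                raise ValueError(f"class {name!r} has empty prompts")
            self.prompts[name] = cleaned
            self.provenance.setdefault(name, ["user-supplied"] * len(cleaned))
        sizes = {len(self.prompts[n]) for n in self.class_names}
        if len(sizes) > 1:
            warnings.warn(
                f"prompt counts differ across classes ({sorted(sizes)}); "
                "call normalize(M) before encoding",
                stacklevel=2,
            )
        if self.M is None:
            self.M = max(sizes)

    def normalize(self, M: int | None = None) -> "PromptBank":
        """Pad (by cycling) or truncate every class list to exactly M."""
        M = M or self.M or DEFAULT_M
        prompts, prov = {}, {}
        for name in self.class_names:
            lst, pv = self.prompts[name], self.provenance[name]
            idx = [i % len(lst) for i in range(M)]
            prompts[name] = [lst[i] for i in idx]
            prov[name] = [pv[i] for i in idx]
        return PromptBank(list(self.class_names), prompts, prov, M)

    def is_uniform(self) -> bool:
        return all(len(self.prompts[n]) == self.M for n in self.class_names)


def generate_prompts(
    captioner: Captioner,
    representatives: dict[str, list[str]],
    get_image: Callable[[str, str], np.ndarray],
    M: int = DEFAULT_M,
) -> PromptBank:
    """One description per representative image, padded/truncated to M.

    ``get_image(class_name, identifier)`` resolves a representative to
    its pixel array.  A captioner failure on one item is recorded and
    the item skipped; a class whose every caption fails is an error.
    If a class has fewer than M captions, its representatives' captions
    are cycled; more than M are truncated.
    """
    if not representatives:
        raise ValueError("no representatives given")
    class_names = sorted(representatives)
    prompts: dict[str, list[str]] = {}
    provenance: dict[str, list[str]] = {}
    tag = "mock" if getattr(captioner, "name", "") == "mock" else "external-captioner"
    for name in class_names:
        query = build_query(name)
        captions = []
        for ident in representatives[name]:
            try:
                text = captioner.describe(get_image(name, ident), query).strip()
                if not text:
                    raise ValueError("empty caption")
                captions.append(text)
            except Exception as exc:  # noqa: BLE001 - captioners are external
                warnings.warn(f"captioner failed on {name}/{ident}: {exc}", stacklevel=2)
        if not captions:
            raise RuntimeError(f"no captions could be generated for class {name!r}")
        idx = [i % len(captions) for i in range(M)]
        prompts[name] = [captions[i] for i in idx]
        provenance[name] = [tag] * M
    return PromptBank(class_names, prompts, provenance, M)


def save_prompt_bank(bank: PromptBank, path: str | Path) -> None:
    payload = {
        "M": bank.M,
        "classes": [
            {
                "name": name,
                "prompts": bank.prompts[name],
                "provenance": bank.provenance[name],
            }
            for name in bank.class_names
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_prompt_bank(path: str | Path) -> PromptBank:
    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict) or "classes" not in data:
        raise ValueError("prompt bank JSON must contain a 'classes' list")
    names, prompts, prov = [], {}, {}
    for entry in data["classes"]:
        if "name" not in entry or "prompts" not in entry:
            raise ValueError(
                f"malformed class entry {entry.get('name', '<unnamed>')!r}: "
                "needs 'name' and 'prompts'"
            )
        if not isinstance(entry["prompts"], list) or not entry["prompts"]:
            raise ValueError(f"class {entry['name']!r} has no prompt list")
        names.append(entry["name"])
        prompts[entry["name"]] = list(entry["prompts"])
        if "provenance" in entry:
            prov[entry["name"]] = list(entry["provenance"])
    return PromptBank(names, prompts, prov, data.get("M"))
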