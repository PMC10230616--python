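"""Diagnosis-code mapping across ICD revisions.

A :class:`CodeMap` maps a disorder label to a set of ``(icd_version, prefix)``
pairs; an event matches a disorder when its code starts with any prefix
registered for the event's ICD revision.  Defaults cover MDD (with provisional
ICD-8/ICD-9 equivalents) and the common comparison disorders, plus self-harm
and ECT procedure codes.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import yaml

__all__ = ["CodeMap", "default_code_map", "CROSSOVER_DISORDERS"]

# disorders whose later diagnosis counts as diagnostic cross-over from MDD
CROSSOVER_DISORDERS = ("bipolar", "schizophrenia")

_DEFAULTS: dict[str, set[tuple[int, str]]] = {
    "mdd": {(10, "F32"), (10, "F33"), (9, "296.2"), (9, "296.3"), (9, "311"),
            (8, "296.0"), (8, "300.4")},
    "mdd_recurrent": {(10, "F33"), (9, "296.3")},
    "asd": {(10, "F84")},
    "adhd": {(10, "F90")},
    "anxiety": {(10, "F40"), (10, "F41")},
    "bipolar": {(10, "F30"), (10, "F31")},
    "eating": {(10, "F50")},
    "schizophrenia": {(10, "F20"), (10, "F25")},
    "substance_use": {(10, "F1")},
    "self_harm": {(10, "X6"), (10, "X7"), (10, "X80"), (10, "X81"),
                  (10, "X82"), (10, "X83"), (10, "X84")},
    "ect": {(10, "DA0")},
}


class CodeMap:
    """Disorder label -> {(icd_version, code prefix)} with prefix matching."""

    def __init__(self, entries: Mapping[str, Iterable[tuple[int, str]]]):
        self._map: dict[str, set[tuple[int, str]]] = {}
        for disorder, pairs in entries.items():
            pairs = {(int(v), str(p)) for v, p in pairs}
            if not pairs or any(not p for _, p in pairs):
                raise ValueError(f"{disorder}: prefixes must be non-empty")
            self._check_no_overlap(disorder, pairs)
            self._map[disorder] = pairs

    @staticmethod
    def _check_no_overlap(disorder: str, pairs: set[tuple[int, str]]) -> None:
        by_version: dict[int, list[str]] = {}
        for v, p in pairs:
            by_version.setdefault(v, []).append(p)
        for v, prefixes in by_version.items():
            prefixes = sorted(prefixes)
            for a, b in zip(prefixes, prefixes[1:]):
                if b.startswith(a):
                    raise ValueError(
                        f"{disorder}: overlapping prefixes {a!r} and {b!r} for ICD-{v}")

    def disorders(self) -> list[str]:
        return sorted(self._map)

    def prefixes(self, disorder: str) -> set[tuple[int, str]]:
        return set(self._map[disorder])

    def matches(self, disorder: str, icd_version: int, code: str) -> bool:
        return any(v == icd_version and code.startswith(p)
                   for v, p in self._map[disorder])

    def match_mask(self, disorder: str, icd_versions, codes):
        """Vectorised membership over parallel sequences of versions and codes."""
        import numpy as np

        icd_versions = np.asarray(icd_versions, dtype=int)
        codes = np.asarray(codes, dtype=str)
        mask = np.zeros(len(codes), dtype=bool)
        for v, p in self._map[disorder]:
            mask |= (icd_versions == v) & np.char.startswith(codes, p)
        return mask

    # -- serialisation ------------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {d: sorted([list(pair) for pair in pairs])
                   for d, pairs in self._map.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CodeMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({d: [tuple(pair) for pair in pairs] for d, pairs in raw.items()})


def default_code_map() -> CodeMap:
    """Shipped defaults.  The ICD-8/ICD-9 MDD equivalents are provisional and
    editable; real register studies should supply their own mapping file."""
    return CodeMap(_DEFAULTS)
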