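"""The catalogue of the 96 imaging biomarkers.

Family census: 24 intensity, 20 geometric and 52 texture features
(GLCM 20, GLRLM 16, NGTDM 5, GLSZM 11).  The registry fixes the names,
families and a stable extraction order; it is asserted consistent at
import time.
"""

from __future__ import annotations

import json

from .geometry import GEOMETRIC_FEATURES
from .intensity import INTENSITY_FEATURES
from .texture import GLCM_FEATURES, GLRLM_FEATURES, GLSZM_FEATURES, NGTDM_FEATURES

__all__ = ["FAMILIES", "FEATURE_NAMES", "feature_family", "registry_json"]

FAMILIES: dict[str, list[str]] = {
    "intensity": list(INTENSITY_FEATURES),
    "geometric": list(GEOMETRIC_FEATURES),
    "GLCM": list(GLCM_FEATURES),
    "GLRLM": list(GLRLM_FEATURES),
    "NGTDM": list(NGTDM_FEATURES),
    "GLSZM": list(GLSZM_FEATURES),
}

_EXPECTED_COUNTS = {
    "intensity": 24,
    "geometric": 20,
    "GLCM": 20,
    "GLRLM": 16,
    "NGTDM": 5,
    "GLSZM": 11,
}

for _fam, _count in _EXPECTED_COUNTS.items():
    assert len(FAMILIES[_fam]) == _count, (
        f"{_fam} family has {len(FAMILIES[_fam])} members, expected {_count}"
    )

#: all 96 feature names in extraction order
FEATURE_NAMES: list[str] = [name for fam in FAMILIES.values() for name in fam]
assert len(FEATURE_NAMES) == 96
assert len(set(FEATURE_NAMES)) == 96, "duplicate feature names in registry"

_NAME_TO_FAMILY = {name: fam for fam, names in FAMILIES.items() for name in names}


def feature_family(name: str) -> str:
    """Family of a registered feature name."""
    try:
        return _NAME_TO_FAMILY[name]
    except KeyError:
        raise KeyError(f"unknown feature {name!r}") from None


def registry_json() -> str:
    """The registry as JSON: one record per feature (name, family)."""
    records = [{"name": n, "family": _NAME_TO_FAMILY[n]} for n in FEATURE_NAMES]
    return json.dumps(records, indent=2)
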