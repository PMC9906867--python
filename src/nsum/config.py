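"""Scale-up configuration: degrees, reference population, correction factors.

The scale-up ratio needs three external quantities that the survey itself
does not provide: the per-gender personal network sizes (degrees) ``c``,
the reference population total ``t``, and the two multiplicative correction
factors — the visibility factor (VF, correcting for alters whose sex work
is hidden from the respondent) and the popularity factor (PF, correcting
for hidden-population members having smaller networks than average).
Defaults reproduce the Kermanshah study conditions: degrees 90 (men) and
120 (women) borrowed from a Kerman study, t = 406,916 adult women from the
2016 census, and factor ranges from the Shiraz correction-factor study —
detection probability 0.35–0.55 (VF its reciprocal, point 1/0.45) and
degree ratio 0.67–0.87 (PF its reciprocal, point 1/0.77).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["NetworkConfig", "load_config"]


@dataclass(frozen=True)
class NetworkConfig:
    """Inputs to the scale-up estimate that are fixed outside the survey.

    Attributes
    ----------
    c_male, c_female : float
        Personal network sizes (average number of adult women known) for
        male and female respondents.
    t : int
        Total reference population the hidden population is scaled to.
    vf_point : float
        Visibility factor point value, the reciprocal of the probability
        that a respondent knows an acquaintance's FSW status.
    vf_range : (float, float)
        Uniform sampling range for VF in Monte Carlo uncertainty runs.
    pf_point : float
        Popularity factor point value, the reciprocal of the hidden-to-
        general degree ratio.
    pf_range : (float, float)
        Uniform sampling range for PF.
    percent_denominator : {"all", "nonmissing"}
        Denominator convention for demographic percentage tables.
    """

    c_male: float = 90.0
    c_female: float = 120.0
    t: int = 406_916
    vf_point: float = 1 / 0.45
    vf_range: tuple[float, float] = (1 / 0.55, 1 / 0.35)
    pf_point: float = 1 / 0.77
    pf_range: tuple[float, float] = (1 / 0.87, 1 / 0.67)
    percent_denominator: str = "all"

    def __post_init__(self) -> None:
        for name in ("c_male", "c_female", "t", "vf_point", "pf_point"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        object.__setattr__(self, "vf_range", tuple(float(x) for x in self.vf_range))
        object.__setattr__(self, "pf_range", tuple(float(x) for x in self.pf_range))
        for name in ("vf_range", "pf_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be an ordered pair of positive numbers")
        if not (self.vf_range[0] <= self.vf_point <= self.vf_range[1]):
            raise ValueError("vf_point must lie within vf_range")
        if not (self.pf_range[0] <= self.pf_point <= self.pf_range[1]):
            raise ValueError("pf_point must lie within pf_range")
        if self.percent_denominator not in ("all", "nonmissing"):
            raise ValueError("percent_denominator must be 'all' or 'nonmissing'")

    def degree(self, gender: Any) -> float:
        """Personal network size for a gender (accepts enum or string)."""
        g = getattr(gender, "value", gender)
        if g == "male":
            return self.c_male
        if g == "female":
            return self.c_female
        raise ValueError(f"unknown gender {gender!r}")

    def scaled_degrees(self, scale: float) -> "NetworkConfig":
        """Copy with both degrees multiplied by ``scale`` (sensitivity runs)."""
        if scale <= 0:
            raise ValueError("scale must be strictly positive")
        return NetworkConfig(
            c_male=self.c_male * scale,
            c_female=self.c_female * scale,
            t=self.t,
            vf_point=self.vf_point,
            vf_range=self.vf_range,
            pf_point=self.pf_point,
            pf_range=self.pf_range,
            percent_denominator=self.percent_denominator,
        )

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "NetworkConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["vf_range"] = list(self.vf_range)
        d["pf_range"] = list(self.pf_range)
        return d


def load_config(path: str | Path) -> NetworkConfig:
    """Load a :class:`NetworkConfig` from a YAML or JSON file.

    The file's keys mirror the dataclass fields; omitted keys fall back to
    the study defaults.  Format is chosen by extension (``.json`` vs
    ``.yaml``/``.yml``; anything else is parsed as YAML, a JSON superset).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return NetworkConfig.from_mapping(data)
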