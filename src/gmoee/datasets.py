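"""Packaged real datasets and synthetic-sample generation.

Four classic positive-valued datasets ship with the package as
one-value-per-line text files (see ``gmoee/data/``):

``aircon_boeing720``
    213 successive failure times (hours) of the air conditioning systems
    of a fleet of 13 Boeing 720 jet airplanes.
``nyc_ozone_1973``
    116 daily ozone level measurements (ppb), New York, May-September 1973.
``wheaton_flood``
    72 exceedances of flood peaks (m^3/s) of the Wheaton River near
    Carcross, Yukon Territory, Canada.
``covid_recovery_m60``
    50 recovery times (days), first positive to first negative COVID-19
    PCR test, males over 60 years old (anonymized Israeli Ministry of
    Health data).

Each fixture is validated on load against its expected count and a stored
SHA-256 checksum of the file contents.
"""

from __future__ import annotations

import hashlib
from importlib import resources

from .core import ParamVector, Sample, rvs
from .io import read_sample

#: name -> (expected n, sha256 of the packaged file)
_CATALOG: dict[str, tuple[int, str]] = {
    "aircon_boeing720": (213, "04d3f6dd42560770cc7944832c77c0ad6fd284bc52eb1083bad974116fc2ebae"),
    "nyc_ozone_1973": (116, "98260b4dbb308e692353def34be78bec73dceada76d40741723c12eca6f06243"),
    "wheaton_flood": (72, "9de97cdc8b3b2e5fd86afd0947b92cd422d66b97b9ce1a8139fa30104dac8e67"),
    "covid_recovery_m60": (50, "d0a025ce5cdb82f05d5d8ec8b9ef12aa8ba02fb65be0c055fb4bf88f9b4af7ee"),
}


def available() -> list[str]:
    """Names of the packaged datasets."""
    return sorted(_CATALOG)


def load(name: str) -> Sample:
    """Load a packaged dataset by name, validating count and checksum."""
    if name not in _CATALOG:
        raise KeyError(f"unknown dataset {name!r}; available: {available()}")
    expected_n, expected_sha = _CATALOG[name]
    ref = resources.files("gmoee.data").joinpath(f"{name}.txt")
    raw = ref.read_bytes()
    sha = hashlib.sha256(raw).hexdigest()
    if sha != expected_sha:
        raise ValueError(f"checksum mismatch for dataset {name!r}")
    with resources.as_file(ref) as path:
        sample = read_sample(path, label=name)
    if sample.n != expected_n:
        raise ValueError(
            f"dataset {name!r} has {sample.n} values, expected {expected_n}"
        )
    return sample


def make_synthetic(eta: ParamVector, n: int, seed=None) -> Sample:
    """A labelled synthetic GMO-EE sample (inverse-transform, seeded)."""
    s = rvs(eta, n, seed=seed)
    return Sample(values=s.values, label=f"synthetic GMO-EE n={n}")
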