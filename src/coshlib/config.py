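"""YAML/JSON configuration loading.

A configuration file contains any of the blocks ``oxyhb``, ``capillary``,
``tissue``, ``solubilities``, ``resistances`` and ``solver``; omitted
blocks (or keys) fall back to the mouse-cortex baseline preset.  All values
are in the package's canonical units (um, s, mmHg, um^3 O2), except that
diffusivities may alternatively be given in cm^2/s via ``*_cgs`` keys.

Example::

    capillary: {r_c: 1.6, r_p: 2.0, r_w: 2.5, mu_LD: 0.3, v_rbc: 1000, L: 100}
    tissue: {spacing: 40, M0: 1.0e-3}
    oxyhb: {kind: hill, n: 2.64, p50: 47.9}
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path
from typing import Optional, Union

import yaml

from coshlib.oxyhb import OxyHbCurve
from coshlib.params import (
    CM2_PER_S_TO_UM2_PER_S,
    krogh_radius_from_spacing,
    mouse_cortex_baseline,
)


def _read(path: Union[str, Path]) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def load_config(path: Optional[Union[str, Path]] = None,
                geometry: str = "single") -> dict:
    """Resolve a configuration file against the baseline preset.

    Returns a dict with keys ``curve``, ``capillary``, ``tissue``, ``sol``,
    ``resistances`` and ``solver`` (a kwargs dict for the discrete solver).
    """
    base = mouse_cortex_baseline(geometry)
    raw = _read(path) if path is not None else {}

    oxy = dict(raw.get("oxyhb", {}))
    if oxy:
        curve = OxyHbCurve(
            kind=oxy.get("kind", "hill"),
            n=float(oxy.get("n", 2.64)),
            p50=float(oxy.get("p50", 47.9)),
            adair_coeffs=tuple(oxy["adair_coeffs"])
            if "adair_coeffs" in oxy else None)
    else:
        curve = base["curve"]

    cap_over = {k: float(v) for k, v in dict(raw.get("capillary", {})).items()}
    capillary = replace(base["capillary"], **cap_over) if cap_over \
        else base["capillary"]

    tis_over = dict(raw.get("tissue", {}))
    if "spacing" in tis_over:
        tis_over["r_t"] = krogh_radius_from_spacing(
            float(tis_over.pop("spacing")))
    if "D_t_cgs" in tis_over:
        tis_over["D_t"] = float(tis_over.pop("D_t_cgs")) \
            * CM2_PER_S_TO_UM2_PER_S
    tis_over = {k: float(v) for k, v in tis_over.items()}
    tissue = replace(base["tissue"], **tis_over) if tis_over \
        else base["tissue"]

    sol_over = {k: float(v) for k, v in
                dict(raw.get("solubilities", {})).items()}
    sol = replace(base["sol"], **sol_over) if sol_over else base["sol"]

    res_over = {k: float(v) for k, v in
                dict(raw.get("resistances", {})).items()}
    resistances = replace(base["resistances"], **res_over) if res_over \
        else base["resistances"]

    solver = dict(raw.get("solver", {}))

    return {"curve": curve, "capillary": capillary, "tissue": tissue,
            "sol": sol, "resistances": resistances, "solver": solver}
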