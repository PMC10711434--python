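"""Serialization of contact-map specs and run provenance.

Contact maps travel as nested YAML (switching block plus one entry per
pair) so a spec built from one structure can be audited, edited and
re-applied. A flat TSV dump of the pairs is provided for eyeballing.
Every CLI command also drops a provenance block (config hash, seeds,
version) next to its outputs so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import yaml

from .atoms import AtomId
from .contacts import ContactMapSpec, ContactPair, SwitchingParams
from .errors import ContactMapError


def _atom_to_dict(a: AtomId) -> dict:
    d = {"chain": a.chain, "resname": a.resname, "resnum": a.resnum, "name": a.name}
    if a.serial is not None:
        d["serial"] = a.serial
    if a.element is not None:
        d["element"] = a.element
    return d


def _atom_from_dict(d: Mapping) -> AtomId:
    return AtomId(
        chain=str(d["chain"]),
        resname=str(d["resname"]),
        resnum=int(d["resnum"]),
        name=str(d["name"]),
        serial=int(d["serial"]) if "serial" in d else None,
        element=str(d["element"]) if "element" in d else None,
    )


def spec_to_dict(spec: ContactMapSpec) -> dict:
    return {
        "switching": {
            "r0": spec.switching.r0,
            "d0": spec.switching.d0,
            "nn": spec.switching.nn,
            "mm": spec.switching.mm,
        },
        "pairs": [
            {
                "donor": _atom_to_dict(p.donor),
                "acceptor": _atom_to_dict(p.acceptor),
                "group": p.group,
            }
            for p in spec.pairs
        ],
    }


def spec_from_dict(data: Mapping) -> ContactMapSpec:
    try:
        sw = data["switching"]
        switching = SwitchingParams(
            r0=float(sw["r0"]), d0=float(sw["d0"]), nn=int(sw["nn"]), mm=int(sw["mm"])
        )
        pairs = tuple(
            ContactPair(
                donor=_atom_from_dict(p["donor"]),
                acceptor=_atom_from_dict(p["acceptor"]),
                group=str(p["group"]),
            )
            for p in data["pairs"]
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ContactMapError(f"malformed contact-map spec: {exc}") from exc
    return ContactMapSpec(pairs=pairs, switching=switching)


def save_spec(spec: ContactMapSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False))


def load_spec(path) -> ContactMapSpec:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, Mapping):
        raise ContactMapError(f"{path}: not a contact-map spec file")
    return spec_from_dict(data)


def spec_to_tsv(spec: ContactMapSpec) -> str:
    """Human-auditable pair table: group, donor, acceptor, serials."""
    lines = ["group\tdonor\tacceptor\tdonor_serial\tacceptor_serial"]
    for p in spec.pairs:
        lines.append(
            f"{p.group}\t{p.donor}\t{p.acceptor}\t"
            f"{p.donor.serial if p.donor.serial is not None else '-'}\t"
            f"{p.acceptor.serial if p.acceptor.serial is not None else '-'}"
        )
    return "\n".join(lines) + "\n"


def provenance_block(command: str, params: Mapping, version: str) -> dict:
    """Machine-readable record of what produced a set of outputs."""
    canonical = json.dumps(
        {"command": command, "params": dict(sorted(params.items()))},
        sort_keys=True,
        default=str,
    )
    return {
        "command": command,
        "params": {k: params[k] for k in sorted(params)},
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "version": version,
    }


def write_provenance(path, command: str, params: Mapping, version: str) -> None:
    Path(path).write_text(
        json.dumps(provenance_block(command, params, version), indent=2, default=str)
        + "\n"
    )
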