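"""JSON model documents and CSV trajectory output.

The model document is a flat JSON description of species, flows,
reactions, advective edges and pipes, validated by a pydantic schema.
Documents round-trip bytewise once canonicalised (sorted keys, two-space
indent, trailing newline).  Results are written as CSV with a ``#`` header
comment recording units, solver settings, model hash and seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .components import AdvectionEdge, FlowProfile, ReactionEdge, SpeciesState
from .errors import ModelValidationError
from .network import NetworkModel, SimulationResult
from .pipe import Pipe

__all__ = [
    "ModelDocument",
    "load_model",
    "save_model",
    "model_to_document",
    "document_to_model",
    "write_result",
    "read_result",
]

SCHEMA_VERSION = 1


class _Doc(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProfileDoc(_Doc):
    kind: Literal["constant", "step", "sinusoid", "piecewise"]
    params: dict


class FlowDoc(ProfileDoc):
    name: str


class SpeciesDoc(_Doc):
    name: str
    K: float = 1.0
    V: float = 1.0
    x0: float = 0.0
    chemostat: bool = False
    profile: Optional[ProfileDoc] = None


class ReactionDoc(_Doc):
    name: str
    kappa: float
    substrates: list[tuple[str, float]]
    products: list[tuple[str, float]]


class AdvectionDoc(_Doc):
    name: str
    upstream: str
    downstream: str
    flow: str
    K_ref: Optional[float] = None


class PipeDoc(_Doc):
    name: str
    V: float
    N: int
    K: float = 1.0
    inlet: Optional[str] = None
    outlet: Optional[str] = None
    flow: str
    K_ref: Optional[float] = None
    x0: float = 0.0


class ModelDocument(_Doc):
    """The on-disk JSON form of a network model."""

    schema_version: int = SCHEMA_VERSION
    name: str = "model"
    RT: float = 1.0
    species: list[SpeciesDoc] = Field(default_factory=list)
    flows: list[FlowDoc] = Field(default_factory=list)
    reactions: list[ReactionDoc] = Field(default_factory=list)
    advections: list[AdvectionDoc] = Field(default_factory=list)
    pipes: list[PipeDoc] = Field(default_factory=list)


def _profile_from_doc(doc: ProfileDoc) -> FlowProfile:
    p = doc.params
    try:
        if doc.kind == "constant":
            return FlowProfile.constant(p["Q0"])
        if doc.kind == "step":
            return FlowProfile.step(p["Q0"], p["Q1"], p["t_step"])
        if doc.kind == "sinusoid":
            return FlowProfile.sinusoid(p["Q0"], p["amplitude"], p["period"])
        return FlowProfile.piecewise(p["times"], p["values"])
    except KeyError as exc:
        raise ModelValidationError(
            f"profile of kind {doc.kind!r} is missing parameter {exc.args[0]!r}"
        ) from None


def _profile_to_doc(profile: FlowProfile) -> dict:
    params = {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in profile.params
    }
    return {"kind": profile.kind, "params": params}


def document_to_model(doc: ModelDocument) -> NetworkModel:
    """Resolve a validated document into a network model."""
    flows = {f.name: _profile_from_doc(f) for f in doc.flows}

    def flow_ref(owner: str, name: str) -> FlowProfile:
        if name not in flows:
            raise ModelValidationError(
                f"{owner} references unknown flow {name!r}"
            )
        return flows[name]

    species = [
        SpeciesState(
            name=s.name,
            x0=s.x0,
            V=s.V,
            K=s.K,
            chemostat=s.chemostat,
            profile=_profile_from_doc(s.profile) if s.profile else None,
        )
        for s in doc.species
    ]
    reactions = [
        ReactionEdge(r.name, r.kappa, list(r.substrates), list(r.products))
        for r in doc.reactions
    ]
    advections = [
        AdvectionEdge(
            a.name,
            a.upstream,
            a.downstream,
            flow_ref(f"advection {a.name!r}", a.flow),
            K_ref=a.K_ref,
        )
        for a in doc.advections
    ]
    pipes = [
        Pipe(
            name=p.name,
            V=p.V,
            N=p.N,
            flow=flow_ref(f"pipe {p.name!r}", p.flow),
            K=p.K,
            inlet=p.inlet,
            outlet=p.outlet,
            K_ref=p.K_ref,
            x0=p.x0,
        )
        for p in doc.pipes
    ]
    model = NetworkModel(
        species=species,
        reactions=reactions,
        advections=advections,
        pipes=pipes,
        RT=doc.RT,
        name=doc.name,
    )
    model.validate()
    return model


def model_to_document(model: NetworkModel) -> ModelDocument:
    """Serialise a network model back to its document form.

    Unified edges and callable profiles/rates have no document
    representation and raise.
    """
    if model.unified:
        raise ModelValidationError("unified edges have no document representation")
    flows: dict[str, FlowProfile] = {}

    def flow_name(profile: FlowProfile) -> str:
        for name, existing in flows.items():
            if existing == profile:
                return name
        name = f"Q{len(flows) + 1}"
        flows[name] = profile
        return name

    advections = []
    for a in model.advections:
        advections.append(
            {
                "name": a.name,
                "upstream": a.upstream,
                "downstream": a.downstream,
                "flow": flow_name(a.flow),
                "K_ref": a.K_ref,
            }
        )
    pipes = []
    for p in model.pipes:
        pipes.append(
            {
                "name": p.name,
                "V": p.V,
                "N": p.N,
                "K": p.K,
                "inlet": p.inlet,
                "outlet": p.outlet,
                "flow": flow_name(p.flow),
                "K_ref": p.K_ref,
                "x0": p.x0,
            }
        )
    species = []
    for s in model.species:
        if s.profile is not None and not isinstance(s.profile, FlowProfile):
            raise ModelValidationError(
                f"species {s.name!r} has a callable profile; not serialisable"
            )
        species.append(
            {
                "name": s.name,
                "K": s.K,
                "V": s.V,
                "x0": s.x0,
                "chemostat": s.chemostat,
                "profile": _profile_to_doc(s.profile) if s.profile else None,
            }
        )
    reactions = []
    for r in model.reactions:
        if callable(r.kappa):
            raise ModelValidationError(
                f"reaction {r.name!r} has a callable rate; not serialisable"
            )
        reactions.append(
            {
                "name": r.name,
                "kappa": float(r.kappa),
                "substrates": [list(x) for x in r.substrates],
                "products": [list(x) for x in r.products],
            }
        )
    return ModelDocument.model_validate(
        {
            "schema_version": SCHEMA_VERSION,
            "name": model.name,
            "RT": model.RT,
            "species": species,
            "flows": [{"name": n, **_profile_to_doc(f)} for n, f in flows.items()],
            "reactions": reactions,
            "advections": advections,
            "pipes": pipes,
        }
    )


def load_model(path) -> NetworkModel:
    """Read and validate a JSON model document."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelValidationError(f"{path}: not valid JSON: {exc}") from None
    try:
        doc = ModelDocument.model_validate(raw)
    except ValidationError as exc:
        fields = "; ".join(
            ".".join(str(loc) for loc in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ModelValidationError(f"{path}: schema violation at {fields}") from None
    return document_to_model(doc)


def canonical_json(doc: ModelDocument) -> str:
    return json.dumps(doc.model_dump(), indent=2, sort_keys=True) + "\n"


def save_model(model_or_doc, path) -> None:
    """Write a model (or document) as canonical JSON."""
    doc = (
        model_or_doc
        if isinstance(model_or_doc, ModelDocument)
        else model_to_document(model_or_doc)
    )
    Path(path).write_text(canonical_json(doc))


def write_result(result: SimulationResult, path, units: str | None = None) -> None:
    """Write a simulation result as CSV with a provenance header comment."""
    frame = result.to_frame()
    if frame.empty:
        raise ValueError("refusing to write an empty result")
    md = result.metadata
    header = [
        "# bondflow trajectory",
        f"# units: {units or 'normalized (time, amounts, flows, powers)'}",
        f"# solver: method={md.get('method')} rtol={md.get('rtol')} atol={md.get('atol')}",
        f"# model: {md.get('model_name')} hash={md.get('model_hash')} seed={md.get('seed')}",
    ]
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        frame.to_csv(fh, index=False, float_format="%.15g")


def read_result(path) -> pd.DataFrame:
    """Read back a trajectory CSV written by :func:`write_result`."""
    return pd.read_csv(path, comment="#")
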