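"""Read/write model, database, mapping and report files.

Formats
-------
* SBML Level-3 + FBC (read/write, delegated to COBRApy);
* a plain TSV model dialect for fixtures and desk work: columns
  ``reaction_id  equation  lb  ub  is_objective`` (optional 6th column
  ``universal_id``), '#' comments, equations in the universal grammar but
  over model metabolite ids with single-sided exchanges allowed
  (``Suc =>`` secretes, ``=> Suc`` feeds);
* universal database TSV: ``reaction_id  equation`` (optional
  ``direction`` column, ``=>`` forcing irreversibility);
* compound map: JSON object or 2-column TSV, host metabolite id ->
  universal compound id (many-to-one allowed);
* screening report TSV with deterministic row order.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

from .model import MetabolicModel, Metabolite, ModelError, Reaction
from .reactions import (
    COMPOUND_ID_RE,
    EquationParseError,
    ReactionEquation,
    _parse_side,
    format_equation,
    parse_equation,
)
from .screen import ScreenResult

__all__ = [
    "CompoundMap",
    "read_compound_map",
    "apply_compound_map",
    "read_model_tsv",
    "write_model_tsv",
    "read_sbml",
    "write_sbml",
    "read_universal_db",
    "write_universal_db",
    "write_screen_report",
]


@dataclass(frozen=True)
class CompoundMap:
    """Host metabolite id -> universal compound id (many-to-one allowed)."""

    entries: dict[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        bad = [c for c in self.entries.values() if not COMPOUND_ID_RE.match(c)]
        if bad:
            raise ValueError(f"malformed universal compound ids: {sorted(set(bad))}")

    @classmethod
    def from_model(cls, model: MetabolicModel) -> "CompoundMap":
        return cls(
            {m.id: m.universal_id for m in model.metabolites.values() if m.universal_id},
            provenance=f"annotations of model {model.id}",
        )


def read_compound_map(path) -> CompoundMap:
    text = open(path, encoding="utf-8").read()
    if text.lstrip().startswith("{"):
        return CompoundMap(json.loads(text), provenance=str(path))
    entries = {}
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
        entries[parts[0]] = parts[1]
    return CompoundMap(entries, provenance=str(path))


def apply_compound_map(model: MetabolicModel, cmap: CompoundMap) -> MetabolicModel:
    """A copy of ``model`` with universal ids set from the map."""
    out = model.copy()
    for mid, cid in cmap.entries.items():
        if mid in out.metabolites:
            out.metabolites[mid].universal_id = cid
    return out


# -- TSV model dialect -----------------------------------------------------


def _parse_bound(tok: str) -> float:
    return float(tok)


def read_model_tsv(path, model_id: Optional[str] = None) -> MetabolicModel:
    """Read the plain TSV model dialect.

    Metabolites are created on first mention; compound-shaped metabolite
    ids (``C`` + 5 digits) double as their universal ids.
    """
    model = MetabolicModel(id=model_id or str(path))
    objective = None
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].rstrip("\n")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split("\t")]
            if parts[0] == "reaction_id":  # optional header
                continue
            if len(parts) < 5:
                raise ValueError(f"{path}:{ln}: expected >=5 columns, got {len(parts)}")
            rid, eq_text, lb, ub, is_obj = parts[:5]
            uid = parts[5] if len(parts) > 5 and parts[5] else None
            stoich = _equation_to_stoichiometry(eq_text, rid)
            for mid in stoich:
                if mid not in model.metabolites:
                    model.metabolites[mid] = Metabolite(
                        id=mid,
                        compartment="c",
                        universal_id=mid if COMPOUND_ID_RE.match(mid) else None,
                    )
            model._insert(
                Reaction(
                    id=rid,
                    stoichiometry=stoich,
                    lower_bound=_parse_bound(lb),
                    upper_bound=_parse_bound(ub),
                    source="host",
                    universal_id=uid,
                )
            )
            if is_obj not in ("0", "1"):
                raise ValueError(f"{path}:{ln}: is_objective must be 0 or 1")
            if is_obj == "1":
                if objective is not None:
                    raise ValueError(f"{path}:{ln}: multiple objective reactions")
                objective = (rid, "max")
    model.objective = objective
    return model


def _equation_to_stoichiometry(text: str, rid: str) -> dict[str, Fraction]:
    if "<=>" in text:
        left, right = text.split("<=>", 1)
    elif "=>" in text:
        left, right = text.split("=>", 1)
    else:
        raise EquationParseError("no reaction arrow found", rid)
    subs = _parse_side(left, rid, allow_empty=True)
    prods = _parse_side(right, rid, allow_empty=True)
    if not subs and not prods:
        raise EquationParseError("both sides empty", rid)
    stoich: dict[str, Fraction] = {}
    for coef, mid in subs:
        stoich[mid] = stoich.get(mid, Fraction(0)) - coef
    for coef, mid in prods:
        stoich[mid] = stoich.get(mid, Fraction(0)) + coef
    return {m: k for m, k in stoich.items() if k != 0}


def _fmt_bound(x: float) -> str:
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return repr(float(x)) if x != int(x) else str(int(x))


def write_model_tsv(model: MetabolicModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("reaction_id\tequation\tlb\tub\tis_objective\tuniversal_id\n")
        for rid, rxn in model.reactions.items():
            subs = [(-k, m) for m, k in rxn.stoichiometry.items() if k < 0]
            prods = [(k, m) for m, k in rxn.stoichiometry.items() if k > 0]
            fmt = lambda side: " + ".join(
                (f"{k} " if k != 1 else "") + m for k, m in side
            )
            eq = f"{fmt(subs)} <=> {fmt(prods)}".strip()
            is_obj = "1" if model.objective and model.objective[0] == rid else "0"
            fh.write(
                f"{rid}\t{eq}\t{_fmt_bound(rxn.lower_bound)}\t"
                f"{_fmt_bound(rxn.upper_bound)}\t{is_obj}\t{rxn.universal_id or ''}\n"
            )


# -- SBML via COBRApy ------------------------------------------------------


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for m in model.metabolites.values():
        cmet = cobra.Metabolite(id=m.id, name=m.name or m.id, compartment=m.compartment or "c")
        if m.universal_id:
            cmet.annotation["kegg.compound"] = m.universal_id
        mets[m.id] = cmet
    for r in model.reactions.values():
        crxn = cobra.Reaction(id=r.id, name=r.name or r.id)
        crxn.lower_bound = r.lower_bound
        crxn.upper_bound = r.upper_bound
        cm.add_reactions([crxn])
        crxn.add_metabolites({mets[m]: float(k) for m, k in r.stoichiometry.items()})
        if r.universal_id:
            crxn.annotation["kegg.reaction"] = r.universal_id
    if model.objective:
        rid, direction = model.objective
        cm.objective = cm.reactions.get_by_id(rid)
        cm.objective_direction = direction
    return cm


def _first_kegg(annotation, pattern) -> Optional[str]:
    raw = annotation.get("kegg.compound") or annotation.get("kegg.reaction")
    if raw is None:
        return None
    values = raw if isinstance(raw, list) else [raw]
    for v in values:
        if pattern.match(v):
            return v
    return None


def _from_cobra(cm) -> MetabolicModel:
    import re as _re

    rxn_pat = _re.compile(r"^R\d{5}$")
    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=m.compartment or "c",
            universal_id=_first_kegg(m.annotation, COMPOUND_ID_RE),
        )
        for m in cm.metabolites
    ]
    rxns = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: Fraction(k).limit_denominator(10**6)
                           for m, k in r.metabolites.items()},
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            name=r.name or "",
            source="host",
            universal_id=_first_kegg(r.annotation, rxn_pat),
        )
        for r in cm.reactions
    ]
    objective = None
    obj_rxns = [r.id for r in cm.reactions if r.objective_coefficient]
    if obj_rxns:
        objective = (obj_rxns[0], cm.objective_direction)
    else:
        warnings.warn("SBML model has no FBC objective; none set", stacklevel=2)
    return MetabolicModel(id=cm.id or "model", metabolites=mets, reactions=rxns,
                          objective=objective)


def read_sbml(path) -> MetabolicModel:
    """Read an SBML Level-3/FBC model; KEGG annotations become universal ids."""
    from cobra.io import read_sbml_model

    return _from_cobra(read_sbml_model(str(path)))


def write_sbml(model: MetabolicModel, path) -> None:
    from cobra.io import write_sbml_model

    write_sbml_model(_to_cobra(model), str(path))


# -- universal database ----------------------------------------------------


def read_universal_db(path, skip_unparseable: bool = True) -> list[ReactionEquation]:
    """Read a universal reaction database TSV.

    Polymer-style entries (``n`` coefficients) are skipped with a warning
    when ``skip_unparseable`` is true; any other malformed equation raises
    naming the row.  Duplicate reaction ids are rejected.
    """
    out: list[ReactionEquation] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].rstrip("\n")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split("\t")]
            if parts[0] in ("reaction_id", "id"):
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected reaction_id<TAB>equation")
            rid, eq_text = parts[0], parts[1]
            if rid in seen:
                raise ValueError(f"{path}:{ln}: duplicate reaction id {rid}")
            try:
                eq = parse_equation(eq_text, rid)
            except EquationParseError as exc:
                if skip_unparseable and exc.token:
                    warnings.warn(f"{path}:{ln}: skipping {rid}: {exc}", stacklevel=2)
                    continue
                raise ValueError(f"{path}:{ln}: {exc}") from exc
            if len(parts) > 2 and parts[2] == "=>":
                eq = ReactionEquation(rid, eq.substrates, eq.products, reversible=False)
            seen.add(rid)
            out.append(eq)
    return out


def write_universal_db(db: Sequence[ReactionEquation], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("reaction_id\tequation\n")
        for eq in db:
            fh.write(f"{eq.reaction_id}\t{format_equation(eq)}\n")


# -- screening report ------------------------------------------------------


def _fmt_flux(x: Optional[float]) -> str:
    if x is None:
        return "NA"
    return f"{x:.6g}"


def write_screen_report(results: Sequence[ScreenResult], path,
                        improved_only: bool = False) -> None:
    """Write the screening table.

    One row per result: n, m, comma-joined sorted reaction ids, integer
    rate of increase (baseline = 100), target flux, status, number and
    ids of newly activated host reactions.  Rows are ordered by rate
    descending, then lexicographic reaction ids — a pure function of the
    result set.
    """
    rows = sorted(
        results,
        key=lambda r: (-(r.rate_of_increase if r.rate_of_increase is not None else -1),
                       r.reaction_ids),
    )
    if improved_only:
        rows = [r for r in rows if r.status == "improved" or r.n == 0]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "n\tm\treaction_ids\trate_of_increase\tflux_to_target\tstatus\t"
            "n_activated\tactivated_reactions\n"
        )
        for r in rows:
            fh.write(
                f"{r.n}\t{r.m}\t{','.join(r.reaction_ids)}\t"
                f"{r.rate_of_increase if r.rate_of_increase is not None else 'NA'}\t"
                f"{_fmt_flux(r.augmented_objective)}\t{r.status}\t"
                f"{r.n_activated}\t{','.join(r.activated_host_reactions)}\n"
            )
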