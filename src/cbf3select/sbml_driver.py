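"""Optional SBML clock driver.

Users who have an SBML encoding of a published clock ODE model (e.g. the
multi-loop Arabidopsis clock whose regulator species drive the CBF3
submodel) can integrate it here instead of using the built-in surrogate
waveforms.  A species map declares which SBML species plays each of the six
regulator roles, e.g. ``{"LHY_CCA1": "cLm", "TOC1": "cT", ...}``.

Requires the ``python-libsbml`` package (``pip install cbf3select[sbml]``).
Scope is deliberately limited to SBML core constructs: reactions with
kinetic laws, rate rules, assignment rules, parameters and compartments.
Events and delay constructs are not supported; light input must be encoded
in the model itself (e.g. as a parameter under an assignment rule).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .clock_driver import SPECIES, WILD_TYPE, ClockTrajectory, Genotype, LightRegime

__all__ = ["validate_species_map", "simulate_sbml_clock"]


def validate_species_map(species_map: Mapping[str, str]) -> dict[str, str]:
    """Check that the map assigns a distinct SBML id to all six regulator roles."""
    missing = [sp for sp in SPECIES if sp not in species_map]
    if missing:
        raise ValueError(f"species map is missing regulator roles: {missing}")
    unknown = [sp for sp in species_map if sp not in SPECIES]
    if unknown:
        raise ValueError(f"species map names unknown regulator roles: {unknown}")
    ids = list(species_map.values())
    if len(set(ids)) != len(ids):
        raise ValueError("species map assigns the same SBML id to multiple roles")
    return dict(species_map)


def simulate_sbml_clock(
    path: str,
    species_map: Mapping[str, str],
    regime: LightRegime,
    genotype: Genotype = WILD_TYPE,
    duration: float = 96.0,
    step: float = 0.25,
) -> ClockTrajectory:
    """Integrate an SBML clock model and expose the six regulator roles.

    The model is integrated with LSODA from its initial state over
    ``duration`` hours; mapped species are clipped at zero and genotype
    knockouts/modifiers are applied to the mapped outputs (mechanistic
    mutant simulation would require editing the SBML model itself).
    """
    try:
        import libsbml
    except ImportError as err:  # pragma: no cover - exercised only without the extra
        raise ImportError(
            "SBML clock mode requires the optional dependency python-libsbml; "
            "install it with: pip install python-libsbml"
        ) from err
    from scipy.integrate import solve_ivp
    from sympy import lambdify, symbols
    from sympy.parsing.sympy_parser import parse_expr

    species_map = validate_species_map(species_map)
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValueError(f"libsbml reported errors reading {path!r}")
    model = doc.getModel()
    if model is None:
        raise ValueError(f"no SBML model found in {path!r}")
    if model.getNumEvents() > 0:
        raise NotImplementedError("SBML events are not supported by this driver")

    consts: dict[str, float] = {"time": 0.0, "t": 0.0}
    for i in range(model.getNumCompartments()):
        comp = model.getCompartment(i)
        consts[comp.getId()] = comp.getSize() if comp.isSetSize() else 1.0
    for i in range(model.getNumParameters()):
        par = model.getParameter(i)
        consts[par.getId()] = par.getValue()

    sp_ids, y0 = [], []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        sp_ids.append(sp.getId())
        y0.append(
            sp.getInitialConcentration()
            if sp.isSetInitialConcentration()
            else (sp.getInitialAmount() if sp.isSetInitialAmount() else 0.0)
        )
    idx = {sid: i for i, sid in enumerate(sp_ids)}

    local = {sid: symbols(sid) for sid in list(consts) + sp_ids}

    def compile_formula(node):
        formula = libsbml.formulaToL3String(node)
        expr = parse_expr(formula.replace("^", "**"), local_dict=local)
        expr = expr.subs([(local[k], v) for k, v in consts.items() if k not in idx])
        return lambdify([local[s] for s in sp_ids], expr, modules="numpy")

    rates = [None] * len(sp_ids)
    assignments = []
    for i in range(model.getNumRules()):
        rule = model.getRule(i)
        var = rule.getVariable()
        if rule.isRate() and var in idx:
            rates[idx[var]] = ("rule", compile_formula(rule.getMath()))
        elif rule.isAssignment():
            assignments.append(var)
    if assignments:
        raise NotImplementedError("SBML assignment rules are not supported by this driver")

    reaction_terms: list[tuple[int, float, object]] = []
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        law = rxn.getKineticLaw()
        if law is None:
            raise ValueError(f"reaction {rxn.getId()!r} has no kinetic law")
        for j in range(law.getNumParameters()):
            par = law.getParameter(j)
            consts[par.getId()] = par.getValue()
            local.setdefault(par.getId(), symbols(par.getId()))
        fn = compile_formula(law.getMath())
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            reaction_terms.append((idx[ref.getSpecies()], -ref.getStoichiometry(), fn))
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            reaction_terms.append((idx[ref.getSpecies()], ref.getStoichiometry(), fn))

    def rhs(_t, y):
        dy = np.zeros_like(y)
        cache: dict[int, float] = {}
        for k, (kind_fn) in enumerate(rates):
            if kind_fn is not None:
                dy[k] = kind_fn[1](*y)
        for tgt, stoich, fn in reaction_terms:
            key = id(fn)
            if key not in cache:
                cache[key] = fn(*y)
            dy[tgt] += stoich * cache[key]
        return dy

    times = np.arange(0.0, duration + 0.5 * step, step)
    sol = solve_ivp(rhs, (0.0, float(times[-1])), np.asarray(y0, float),
                    t_eval=times, method="LSODA", rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"SBML clock integration failed: {sol.message}")

    baseline = {
        role: np.clip(sol.y[idx[sbml_id]], 0.0, None) for role, sbml_id in species_map.items()
    }
    traj = ClockTrajectory(times=times, abundances=baseline, regime=regime, baseline=baseline)
    if genotype is not WILD_TYPE:
        traj = traj.with_genotype(genotype)
    return traj
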