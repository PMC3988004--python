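"""Construction of the reduced clock model and the CHRONO extension.

Reduced model
-------------
A deliberately small sequestration-only TTFL intended to reproduce the
*qualitative* genotype ladder of the mammalian clock (periods ordered
Cry1-KO < WT < Chrono-KO, damped Cry1/Cry2 double knockout, arrhythmic
triple knockout) rather than any particular published equation set.  State
variables (concentrations in a.u., time in hours):

* mRNAs for the E-box genes *Per1*, *Per2*, *Cry1*, *Cry2*, *Chrono*,
  *Rev* (the lumped *Rev-erb* pair) and for *Bmal1*;
* cytoplasmic proteins PER (lumped PER1/PER2 pool), CRY1, CRY2, CHRONO;
* nuclear REV-ERB and the free BMAL1--CLOCK activator pool;
* three nuclear repressor pools -- PER·CRY1, PER·CRY2 and PER·CHRONO
  (CHRONO reaches the nucleus in complex with PER2, with the same import
  kinetics as the PER--CRY complexes) -- and the corresponding inactive
  activator complexes formed by 1:1 sequestration.

E-box transcription is ``basal + vmax * A/(K + A)`` in the *free* activator
A; all repression acts by mass-action sequestration of A, never through an
explicit Hill repression term.  *Bmal1* transcription is repressed by
nuclear REV-ERB through ``vmax * K_rep/(K_rep + REV)``.

The CRY1 channel is parameterized as the strong/slow repressor (slower
dissociation from the activator and slower clearance than the CRY2
channel); the CHRONO channel is weak/fast, kinetically close to CRY2.
*Chrono* mRNA degradation is tied to the *same parameter symbol* as
*Per2*'s, reflecting their near-identical mRNA time courses.

Detailed mode
-------------
:func:`build_detailed_model` augments a user-supplied base-model definition
(the published ~180-variable mammalian clock model, serialized in this
package's ModelSpec JSON schema) with *Chrono* mRNA dynamics and every
CHRONO-containing complex permitted by the binding rules.  The base model
is not bundled with the package and must be provided by the user.
"""

from __future__ import annotations

import os

import yaml

from .network import (
    CHRONO_BINDING_RULES,
    CYTOPLASM,
    NUCLEUS,
    ConfigurationError,
    ModelSpec,
    Reaction,
    Species,
    TranscriptionRule,
    enumerate_chrono_complexes,
)

__all__ = [
    "DEFAULT_PARAMS_REDUCED_V1",
    "REQUIRED_PARAMS",
    "build_reduced_model",
    "build_detailed_model",
    "load_config",
]

# ---------------------------------------------------------------------------
# committed default parameter set "default_reduced_v1"
#
# Tuned so that the wild-type limit cycle is sustained with a robust Per2
# mRNA rhythm and the in-silico genetics reproduce the observed phenotype
# ladder; the overall time scale is then fixed exactly by uniform rate
# rescaling (see dynamics.calibrate_period) to a 23.8 h wild-type period.
# Units: vmax_*/basal_*/oe_* a.u. h^-1; deg_*/clr_*/seq_off_* h^-1;
# assoc_*/seq_on (a.u. h)^-1; K_* a.u.
# ---------------------------------------------------------------------------

from .params_default import (  # noqa: E402
    DEFAULT_INITIAL_STATE,
    DEFAULT_PARAMS_REDUCED_V1,
)

REQUIRED_PARAMS = (
    "vmax_Per1", "vmax_Per2", "vmax_Cry1", "vmax_Cry2", "vmax_Chrono",
    "vmax_Rev", "vmax_Bmal1",
    "basal_Per1", "basal_Per2", "basal_Cry1", "basal_Cry2", "basal_Chrono",
    "basal_Rev",
    "K_act", "K_rep_Bmal1",
    "deg_M_Per1", "deg_M_Per2", "deg_M_Cry1", "deg_M_Cry2", "deg_M_Rev",
    "deg_M_Bmal1",
    "tl_Per", "tl_Cry1", "tl_Cry2", "tl_Chrono", "tl_Rev", "tl_Bmal1",
    "deg_PER", "deg_CRY1", "deg_CRY2", "deg_CHRONO", "deg_REV", "deg_A",
    "assoc_PER_CRY1", "assoc_PER_CRY2", "assoc_PER_CHRONO",
    "seq_on", "seq_off_PC1", "seq_off_PC2", "seq_off_CHR",
    "deg_R_PC1", "deg_R_PC2", "deg_R_CHR",
    "clr_C_PC1", "clr_C_PC2", "clr_C_CHR",
)

# species name constants used across the package
M_PER1, M_PER2 = "Per1_mRNA", "Per2_mRNA"
M_CRY1, M_CRY2 = "Cry1_mRNA", "Cry2_mRNA"
M_CHRONO, M_REV, M_BMAL1 = "Chrono_mRNA", "Rev_mRNA", "Bmal1_mRNA"
PER, CRY1, CRY2, CHRONO = "PER@cyt", "CRY1@cyt", "CRY2@cyt", "CHRONO@cyt"
REV, ACTIVATOR = "REV@nuc", "BMAL1_CLOCK@nuc"
R_PC1, R_PC2, R_CHR = "CRY1:PER@nuc", "CRY2:PER@nuc", "CHRONO:PER@nuc"
C_PC1 = "BMAL1_CLOCK:CRY1:PER@nuc"
C_PC2 = "BMAL1_CLOCK:CRY2:PER@nuc"
C_CHR = "BMAL1_CLOCK:CHRONO:PER@nuc"

DEFAULT_REPORTER = M_PER2

_CHRONO_SPECIES = (M_CHRONO, CHRONO, R_CHR, C_CHR)


def load_config(path_or_dict=None) -> dict:
    """Load a YAML config file (or pass a dict through)."""
    if path_or_dict is None:
        return {}
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        out = yaml.safe_load(fh) or {}
    if not isinstance(out, dict):
        raise ConfigurationError(f"config {path_or_dict!r} must be a mapping")
    return out


def build_reduced_model(config=None) -> ModelSpec:
    """Build the reduced clock model from the committed parameter set.

    ``config`` (dict or YAML path) keys:

    * ``parameters``: mapping of parameter overrides;
    * ``chrono_enabled`` (default True): drop every CHRONO-containing
      species and reaction when False;
    * ``parameter_set``: name recorded in metadata (default
      ``"default_reduced_v1"``).
    """
    cfg = load_config(config)
    chrono = bool(cfg.get("chrono_enabled", True))
    params = dict(DEFAULT_PARAMS_REDUCED_V1)
    params.update(cfg.get("parameters", {}))
    missing = [k for k in REQUIRED_PARAMS if params.get(k) is None]
    if missing:
        raise ConfigurationError(
            "parameter set missing required keys: " + ", ".join(missing)
        )

    species = [
        Species(M_PER1, CYTOPLASM, "mRNA"),
        Species(M_PER2, CYTOPLASM, "mRNA"),
        Species(M_CRY1, CYTOPLASM, "mRNA"),
        Species(M_CRY2, CYTOPLASM, "mRNA"),
        Species(M_CHRONO, CYTOPLASM, "mRNA"),
        Species(M_REV, CYTOPLASM, "mRNA"),
        Species(M_BMAL1, CYTOPLASM, "mRNA"),
        Species(PER, CYTOPLASM, "monomer"),
        Species(CRY1, CYTOPLASM, "monomer"),
        Species(CRY2, CYTOPLASM, "monomer"),
        Species(CHRONO, CYTOPLASM, "monomer"),
        Species(REV, NUCLEUS, "monomer"),
        Species(ACTIVATOR, NUCLEUS, "monomer"),
        Species(R_PC1, NUCLEUS, "complex", ("CRY1", "PER")),
        Species(R_PC2, NUCLEUS, "complex", ("CRY2", "PER")),
        Species(R_CHR, NUCLEUS, "complex", ("CHRONO", "PER")),
        Species(C_PC1, NUCLEUS, "complex", ("BMAL1_CLOCK", "CRY1", "PER")),
        Species(C_PC2, NUCLEUS, "complex", ("BMAL1_CLOCK", "CRY2", "PER")),
        Species(C_CHR, NUCLEUS, "complex", ("BMAL1_CLOCK", "CHRONO", "PER")),
    ]

    rxn = []

    def r(reactants, products, k, label):
        rxn.append(Reaction(tuple(reactants), tuple(products), k, label))

    # translation (catalytic in the mRNA); PER is the lumped PER1/PER2 pool
    r([(M_PER1, 1)], [(M_PER1, 1), (PER, 1)], "tl_Per", "Per1 translation")
    r([(M_PER2, 1)], [(M_PER2, 1), (PER, 1)], "tl_Per", "Per2 translation")
    r([(M_CRY1, 1)], [(M_CRY1, 1), (CRY1, 1)], "tl_Cry1", "Cry1 translation")
    r([(M_CRY2, 1)], [(M_CRY2, 1), (CRY2, 1)], "tl_Cry2", "Cry2 translation")
    r([(M_CHRONO, 1)], [(M_CHRONO, 1), (CHRONO, 1)], "tl_Chrono", "Chrono translation")
    r([(M_REV, 1)], [(M_REV, 1), (REV, 1)], "tl_Rev", "Rev translation")
    r([(M_BMAL1, 1)], [(M_BMAL1, 1), (ACTIVATOR, 1)], "tl_Bmal1",
      "BMAL1-CLOCK production")
    # protein turnover
    r([(PER, 1)], [], "deg_PER", "PER degradation")
    r([(CRY1, 1)], [], "deg_CRY1", "CRY1 degradation")
    r([(CRY2, 1)], [], "deg_CRY2", "CRY2 degradation")
    r([(CHRONO, 1)], [], "deg_CHRONO", "CHRONO degradation")
    r([(REV, 1)], [], "deg_REV", "REV degradation")
    r([(ACTIVATOR, 1)], [], "deg_A", "activator degradation")
    # repressor-pool formation (cytoplasmic binding + nuclear import, lumped)
    r([(PER, 1), (CRY1, 1)], [(R_PC1, 1)], "assoc_PER_CRY1", "PER-CRY1 import")
    r([(PER, 1), (CRY2, 1)], [(R_PC2, 1)], "assoc_PER_CRY2", "PER-CRY2 import")
    r([(PER, 1), (CHRONO, 1)], [(R_CHR, 1)], "assoc_PER_CHRONO",
      "PER2-CHRONO import")
    r([(R_PC1, 1)], [], "deg_R_PC1", "PER-CRY1 degradation")
    r([(R_PC2, 1)], [], "deg_R_PC2", "PER-CRY2 degradation")
    r([(R_CHR, 1)], [], "deg_R_CHR", "PER-CHRONO degradation")
    # 1:1 sequestration of the activator
    r([(ACTIVATOR, 1), (R_PC1, 1)], [(C_PC1, 1)], "seq_on", "A+PC1 binding")
    r([(C_PC1, 1)], [(ACTIVATOR, 1), (R_PC1, 1)], "seq_off_PC1", "A.PC1 release")
    r([(ACTIVATOR, 1), (R_PC2, 1)], [(C_PC2, 1)], "seq_on", "A+PC2 binding")
    r([(C_PC2, 1)], [(ACTIVATOR, 1), (R_PC2, 1)], "seq_off_PC2", "A.PC2 release")
    r([(ACTIVATOR, 1), (R_CHR, 1)], [(C_CHR, 1)], "seq_on", "A+CHR binding")
    r([(C_CHR, 1)], [(ACTIVATOR, 1), (R_CHR, 1)], "seq_off_CHR", "A.CHR release")
    # inactive complexes are cleared whole (activator co-degrades with the
    # repressor), so knockouts dispose of stored activator on the clearance
    # timescale rather than hoarding it
    r([(C_PC1, 1)], [], "clr_C_PC1", "A:PC1 complex clearance")
    r([(C_PC2, 1)], [], "clr_C_PC2", "A:PC2 complex clearance")
    r([(C_CHR, 1)], [], "clr_C_CHR", "A:CHR complex clearance")

    ebox = dict(mode="sequestration", activator=ACTIVATOR, k_act_param="K_act")
    rules = [
        TranscriptionRule("Per1", M_PER1, PER, vmax_param="vmax_Per1",
                          basal_param="basal_Per1",
                          degradation_param="deg_M_Per1", **ebox),
        TranscriptionRule("Per2", M_PER2, PER, vmax_param="vmax_Per2",
                          basal_param="basal_Per2",
                          degradation_param="deg_M_Per2", **ebox),
        TranscriptionRule("Cry1", M_CRY1, CRY1, vmax_param="vmax_Cry1",
                          basal_param="basal_Cry1",
                          degradation_param="deg_M_Cry1", **ebox),
        TranscriptionRule("Cry2", M_CRY2, CRY2, vmax_param="vmax_Cry2",
                          basal_param="basal_Cry2",
                          degradation_param="deg_M_Cry2", **ebox),
        # Chrono mRNA decays with Per2's rate parameter (same symbol)
        TranscriptionRule("Chrono", M_CHRONO, CHRONO, vmax_param="vmax_Chrono",
                          basal_param="basal_Chrono",
                          degradation_param="deg_M_Per2", **ebox),
        TranscriptionRule("Rev", M_REV, REV, vmax_param="vmax_Rev",
                          basal_param="basal_Rev",
                          degradation_param="deg_M_Rev", **ebox),
        TranscriptionRule("Bmal1", M_BMAL1, ACTIVATOR, mode="hill_repression",
                          repressor=REV, vmax_param="vmax_Bmal1",
                          k_rep_param="K_rep_Bmal1",
                          degradation_param="deg_M_Bmal1"),
    ]

    if not chrono:
        chrono_set = set(_CHRONO_SPECIES)
        species = [s for s in species if s.name not in chrono_set]
        rxn = [
            x for x in rxn
            if not any(n in chrono_set for n, _ in x.reactants + x.products)
        ]
        rules = [t for t in rules if t.gene != "Chrono"]

    meta = {
        "parameter_set": cfg.get("parameter_set", "default_reduced_v1"),
        "reporter": DEFAULT_REPORTER,
        "chrono_enabled": chrono,
    }
    if "initial_state" in cfg:
        meta["initial_state"] = dict(cfg["initial_state"])
    elif DEFAULT_INITIAL_STATE and chrono and not cfg.get("parameters"):
        meta["initial_state"] = dict(DEFAULT_INITIAL_STATE)

    return ModelSpec(
        species=species,
        reactions=rxn,
        transcription_rules=rules,
        parameters=params,
        mode="reduced",
        binding_rules=CHRONO_BINDING_RULES,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# detailed mode: CHRONO extension of a user-supplied base model
# ---------------------------------------------------------------------------

def build_detailed_model(base_definition_file, config=None) -> ModelSpec:
    """Extend an externally supplied detailed clock model with CHRONO.

    The base model (the published large mammalian clock model) must be a
    ModelSpec JSON document supplied by the user -- it is not bundled.  The
    extension adds *Chrono* mRNA dynamics, the CHRONO protein, and every
    CHRONO-containing complex permitted by the binding rules, pairing each
    new complex with association/dissociation reactions against the existing
    species it extends.  The number of newly added state variables is
    recorded in ``metadata["newly_added_variable_count"]``.
    """
    cfg = load_config(config)
    if base_definition_file is None or not os.path.exists(str(base_definition_file)):
        raise ConfigurationError(
            "detailed mode requires external base model: supply the published "
            "clock-model definition as a ModelSpec JSON file"
        )
    try:
        base = ModelSpec.from_json(base_definition_file)
    except ConfigurationError:
        raise
    except Exception as exc:  # malformed file: report location
        raise ConfigurationError(
            f"malformed base model file {base_definition_file!r}: {exc}"
        ) from exc
    if not base.species:
        raise ConfigurationError("base model invalid: zero species")
    if any("CHRONO" in s.constituents or s.name.startswith("CHRONO")
           for s in base.species):
        raise ConfigurationError(
            "CHRONO species already present: extension applied twice?"
        )

    rules = cfg.get("binding_rules") or CHRONO_BINDING_RULES
    max_size = int(cfg.get("max_complex_size", 3))
    monomer_names = {s.name.split("@")[0] for s in base.species if s.kind == "monomer"}
    partners = sorted(monomer_names & rules.monomers())

    complexes = enumerate_chrono_complexes(partners, rules, max_size)

    new = base.copy()
    new.mode = "detailed"
    params = new.parameters
    new_species = [
        Species(M_CHRONO, CYTOPLASM, "mRNA"),
        Species(CHRONO, CYTOPLASM, "monomer"),
    ] + complexes
    new.species = list(base.species) + new_species

    # Chrono mRNA: E-box driven; degradation tied to Per2's parameter when
    # the base model declares one, otherwise a dedicated parameter
    per2 = next((t for t in base.transcription_rules if t.gene == "Per2"), None)
    deg_param = per2.degradation_param if per2 is not None else "deg_M_Chrono"
    if deg_param not in params:
        params[deg_param] = float(cfg.get("deg_M_Chrono", 0.3))
    activator = per2.activator if per2 is not None else None
    for pname, default in (
        ("vmax_Chrono", 0.5), ("basal_Chrono", 0.01), ("tl_Chrono", 0.3),
        ("deg_CHRONO", 0.3), ("K_act_Chrono", 0.1),
    ):
        params.setdefault(pname, float(cfg.get(pname, default)))
    new.transcription_rules = list(base.transcription_rules) + [
        TranscriptionRule(
            "Chrono", M_CHRONO, CHRONO, mode="sequestration",
            activator=activator, vmax_param="vmax_Chrono",
            basal_param="basal_Chrono",
            k_act_param=per2.k_act_param if per2 is not None else "K_act_Chrono",
            degradation_param=deg_param,
        )
    ]

    new_rxns = list(base.reactions)
    new_rxns.append(Reaction(((M_CHRONO, 1),), ((M_CHRONO, 1), (CHRONO, 1)),
                             "tl_Chrono", "Chrono translation"))
    new_rxns.append(Reaction(((CHRONO, 1),), (), "deg_CHRONO",
                             "CHRONO degradation"))
    by_constituents = {tuple(sorted(s.constituents)): s
                       for s in new_species if s.kind == "complex"}
    name_of_monomer = {s.name.split("@")[0]: s.name for s in new.species
                       if s.kind == "monomer"}
    for cx in complexes:
        members = cx.constituents
        # assemble the complex by adding one monomer to the next-smaller
        # CHRONO complex (or to CHRONO itself for dimers)
        for drop in members:
            if drop == "CHRONO" and len(members) > 2:
                continue
            rest = tuple(sorted(m for m in members if m != drop))
            if len(rest) == 1:
                partner = name_of_monomer.get(rest[0])
            else:
                sub = by_constituents.get(rest)
                partner = sub.name if sub is not None else None
            mono = name_of_monomer.get(drop)
            if partner is None or mono is None:
                continue
            on = f"assoc_CHRONO_cx_{len(members)}"
            off = f"dissoc_CHRONO_cx_{len(members)}"
            params.setdefault(on, float(cfg.get("assoc_default", 1.0)))
            params.setdefault(off, float(cfg.get("dissoc_default", 0.5)))
            new_rxns.append(Reaction(((partner, 1), (mono, 1)), ((cx.name, 1),),
                                     on, f"{cx.name} assembly"))
            new_rxns.append(Reaction(((cx.name, 1),), ((partner, 1), (mono, 1)),
                                     off, f"{cx.name} disassembly"))
            break
        params.setdefault("deg_CHRONO_cx", float(cfg.get("deg_CHRONO_cx", 0.3)))
        new_rxns.append(Reaction(((cx.name, 1),), (), "deg_CHRONO_cx",
                                 f"{cx.name} degradation"))
    new.reactions = new_rxns
    new.metadata = dict(base.metadata)
    new.metadata.update(
        mode="detailed",
        newly_added_variable_count=len(new_species),
        chrono_extension=True,
    )
    new.validate()
    return new


# ---------------------------------------------------------------------------
# frozen numbers for default_reduced_v1 (see module docstring); the WT
# limit-cycle snapshot used as the standard initial condition is stored
# alongside so knockout runs can start from the wild-type cycle.
# ---------------------------------------------------------------------------

DEFAULT_INITIAL_STATE: dict[str, float] = {}
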