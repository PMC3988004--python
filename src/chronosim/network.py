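"""Reaction-network representation of the mammalian circadian clock.

The clock is modelled as a transcription--translation feedback loop (TTFL)
in which the BMAL1--CLOCK activator drives E-box genes (*Per1*, *Per2*,
*Cry1*, *Cry2*, *Rev-erb*, *Chrono*) and is inhibited by stoichiometric
sequestration: repressor complexes bind the activator 1:1 into inactive
complexes rather than acting through a Hill repression term.  CHRONO forms
a second, CRY-independent repression channel; its protein--protein contacts
(binds BMAL1, PER2, CRY2 and DEC2 but not PER1, CRY1 or DEC1, and the
CHRONO--CRY2 contact is deliberately not modelled) are encoded as
:class:`BindingRule` objects and drive rule-based complex enumeration.

Everything here is plain data plus pure transformations; numerical
integration lives in :mod:`chronosim.dynamics`.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

__all__ = [
    "Species",
    "BindingRule",
    "BindingRuleSet",
    "Reaction",
    "TranscriptionRule",
    "ModelSpec",
    "GeneticPerturbation",
    "ConfigurationError",
    "enumerate_chrono_complexes",
    "apply_perturbation",
    "apply_perturbations",
    "parse_perturbations",
    "canonical_complex_name",
]

SCHEMA_VERSION = "1"

CYTOPLASM = "cytoplasm"
NUCLEUS = "nucleus"

_COMPARTMENT_SUFFIX = {CYTOPLASM: "@cyt", NUCLEUS: "@nuc"}


class ConfigurationError(ValueError):
    """A model description is internally inconsistent or incomplete."""


@dataclass(frozen=True)
class Species:
    """One state variable: an mRNA, a protein monomer, or a complex.

    ``constituents`` lists the monomer content of a complex (at least two
    entries); it is empty for mRNAs and monomers.  Concentrations are in
    arbitrary units (a.u.); time is in hours throughout the package.
    """

    name: str
    compartment: str = CYTOPLASM
    kind: str = "monomer"  # mRNA | monomer | complex
    constituents: tuple = ()

    def __post_init__(self):
        if self.compartment not in (CYTOPLASM, NUCLEUS):
            raise ConfigurationError(f"unknown compartment {self.compartment!r}")
        if self.kind not in ("mRNA", "monomer", "complex"):
            raise ConfigurationError(f"unknown species kind {self.kind!r}")
        if self.kind == "complex" and len(self.constituents) < 2:
            raise ConfigurationError(
                f"complex {self.name!r} needs >=2 constituents, got {self.constituents}"
            )
        if self.kind != "complex" and self.constituents:
            raise ConfigurationError(f"{self.kind} {self.name!r} cannot have constituents")


@dataclass(frozen=True)
class BindingRule:
    """Whether two monomers may be in direct contact, and with what kinetics.

    Rates are only meaningful for allowed pairs; ``association_rate`` is in
    1/(a.u.·h) and ``dissociation_rate`` in 1/h.
    """

    partner_a: str
    partner_b: str
    allowed: bool
    association_rate: float = 0.0
    dissociation_rate: float = 0.0

    @property
    def pair(self) -> frozenset:
        return frozenset((self.partner_a, self.partner_b))


class BindingRuleSet:
    """Symmetric lookup table of pairwise binding rules."""

    def __init__(self, rules):
        self._rules = {}
        for r in rules:
            self._rules[r.pair] = r

    def __iter__(self):
        return iter(self._rules.values())

    def __len__(self):
        return len(self._rules)

    def monomers(self) -> set:
        out = set()
        for pair in self._rules:
            out |= set(pair)
        return out

    def allowed(self, a: str, b: str) -> bool:
        rule = self._rules.get(frozenset((a, b)))
        return rule is not None and rule.allowed

    def has_rule(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self._rules


#: CHRONO contact map established by co-immunoprecipitation: CHRONO binds
#: BMAL1, PER2, CRY2 and DEC2 but not PER1, CRY1 or DEC1.  The CHRONO-CRY2
#: contact, although observed, is not represented in the clock model because
#: CHRONO repression does not require CRY2; it is therefore disallowed here.
CHRONO_BINDING_RULES = BindingRuleSet(
    [
        BindingRule("CHRONO", "BMAL1", True, 1.0, 0.5),
        BindingRule("CHRONO", "PER2", True, 1.0, 0.5),
        BindingRule("CHRONO", "CRY2", False),
        BindingRule("CHRONO", "DEC2", True, 1.0, 0.5),
        BindingRule("CHRONO", "PER1", False),
        BindingRule("CHRONO", "CRY1", False),
        BindingRule("CHRONO", "DEC1", False),
    ]
)


def canonical_complex_name(constituents, compartment=NUCLEUS) -> str:
    """Deterministic complex name: sorted constituents joined by ':'."""
    return ":".join(sorted(constituents)) + _COMPARTMENT_SUFFIX[compartment]


def enumerate_chrono_complexes(base_monomers, rules: BindingRuleSet, max_size: int):
    """Enumerate every complex containing CHRONO allowed by the contact rules.

    A candidate complex is a subset of ``base_monomers`` plus CHRONO in which
    *every* pair of distinct constituents is an allowed contact (clique
    semantics: a forbidden pair never appears in any complex, however the
    complex might be assembled).  Output is sorted by (size, name) so the
    result is deterministic.

    Parameters
    ----------
    base_monomers : iterable of str
        Potential partners (CHRONO itself may be included or not).
    rules : BindingRuleSet
        Must contain a rule for every pair involving CHRONO.
    max_size : int
        Largest complex size (number of monomers, >= 2).
    """
    if max_size < 2:
        raise ConfigurationError("max_size must be >= 2")
    base = set(base_monomers) - {"CHRONO"}
    # the rule set is the universe: every base monomer must have an explicit
    # CHRONO rule, or the configuration is inconsistent
    missing = [m for m in sorted(base) if not rules.has_rule("CHRONO", m)]
    if missing:
        raise ConfigurationError(
            f"no CHRONO binding rule for monomer(s): {', '.join(missing)}"
        )
    partners = sorted(m for m in base if rules.allowed("CHRONO", m))
    out = []
    for size in range(2, max_size + 1):
        for combo in itertools.combinations(partners, size - 1):
            members = ("CHRONO",) + combo
            # clique semantics: a pair with an explicit forbidding rule must
            # never co-occur; pairs without a rule (non-CHRONO contacts) are
            # permitted
            ok = all(
                not (rules.has_rule(a, b) and not rules.allowed(a, b))
                for a, b in itertools.combinations(members, 2)
            )
            if ok:
                out.append(
                    Species(
                        name=canonical_complex_name(members),
                        compartment=NUCLEUS,
                        kind="complex",
                        constituents=tuple(sorted(members)),
                    )
                )
    out.sort(key=lambda s: (len(s.constituents), s.name))
    return out


@dataclass(frozen=True)
class Reaction:
    """Mass-action reaction.  ``rate_param`` names an entry in the parameter
    table; the propensity is ``k * prod(conc_i ** stoich_i)`` over reactants.
    """

    reactants: tuple  # tuple of (species_name, stoichiometry)
    products: tuple
    rate_param: str
    label: str = ""


SEQUESTRATION = "sequestration"
HILL_REPRESSION = "hill_repression"


@dataclass(frozen=True)
class TranscriptionRule:
    """Production rule for one gene's mRNA.

    ``sequestration`` mode: rate = basal + vmax * A / (K + A) with A the free
    activator concentration -- repression is implicit, through mass-action
    sequestration of the activator by repressor complexes declared as
    reactions.  ``hill_repression`` mode (used for *Bmal1*, repressed by
    REV-ERB): rate = vmax * K_rep / (K_rep + R).
    """

    gene: str
    mrna: str
    protein: str
    mode: str = SEQUESTRATION
    activator: str | None = None
    vmax_param: str = ""
    basal_param: str | None = None
    k_act_param: str | None = None
    repressor: str | None = None
    k_rep_param: str | None = None
    degradation_param: str = ""


@dataclass
class GeneticPerturbation:
    """A single in-silico genetic manipulation of one gene.

    * ``knockout`` -- transcription (vmax and basal) set to zero and the
      gene's mRNA forced to zero at ``onset_time`` (simulated day 0).
    * ``knockdown`` -- transcription rates multiplied by ``fraction``
      (e.g. 0.3 leaves 30% of the original transcription).
    * ``overexpress`` -- a constitutive, E-box-independent production term
      of ``extra_production`` a.u./h added for the gene's protein.
    """

    gene: str
    action: str  # knockout | knockdown | overexpress
    fraction: float | None = None
    extra_production: float | None = None
    onset_time: float = 0.0

    def __post_init__(self):
        if self.action not in ("knockout", "knockdown", "overexpress"):
            raise ConfigurationError(f"unknown action {self.action!r}")
        if self.action == "knockdown":
            if self.fraction is None or not (0.0 < self.fraction <= 1.0):
                raise ConfigurationError("knockdown requires 0 < fraction <= 1")
        if self.action == "overexpress":
            if self.extra_production is not None and self.extra_production <= 0:
                raise ConfigurationError("overexpress requires extra_production > 0")

    @property
    def label(self) -> str:
        if self.action == "knockout":
            return f"{self.gene}:ko"
        if self.action == "knockdown":
            return f"{self.gene}:kd:{self.fraction:g}"
        if self.extra_production is None:
            return f"{self.gene}:oe"
        return f"{self.gene}:oe:{self.extra_production:g}"


@dataclass
class ModelSpec:
    """Complete declarative model: species, reactions, transcription rules,
    parameters.  Pure data; integration is done by :mod:`chronosim.dynamics`.
    """

    species: list
    reactions: list
    transcription_rules: list
    parameters: dict
    mode: str = "reduced"
    binding_rules: BindingRuleSet | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- introspection -------------------------------------------------
    @property
    def species_names(self):
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    @property
    def genes(self):
        return [r.gene for r in self.transcription_rules]

    def transcription_rule(self, gene: str) -> TranscriptionRule:
        for r in self.transcription_rules:
            if r.gene == gene:
                return r
        raise ConfigurationError(
            f"unknown gene {gene!r}; available: {', '.join(self.genes)}"
        )

    @property
    def perturbations(self):
        return list(self.metadata.get("perturbations", []))

    def validate(self):
        names = self.species_names
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate species names: {dupes}")
        declared = set(names)
        for rxn in self.reactions:
            for sname, stoich in rxn.reactants + rxn.products:
                if sname not in declared:
                    raise ConfigurationError(
                        f"reaction {rxn.label or rxn.rate_param}: undeclared species {sname!r}"
                    )
                if not (isinstance(stoich, int) and stoich >= 1):
                    raise ConfigurationError(
                        f"reaction {rxn.label or rxn.rate_param}: stoichiometry must be int >= 1"
                    )
            if rxn.rate_param not in self.parameters:
                raise ConfigurationError(f"missing rate parameter {rxn.rate_param!r}")
        for tr in self.transcription_rules:
            for pname in (tr.vmax_param, tr.basal_param, tr.k_act_param,
                          tr.k_rep_param, tr.degradation_param):
                if pname and pname not in self.parameters:
                    raise ConfigurationError(
                        f"gene {tr.gene}: missing parameter {pname!r}"
                    )
            for sname in (tr.mrna, tr.protein, tr.activator, tr.repressor):
                if sname and sname not in declared:
                    raise ConfigurationError(
                        f"gene {tr.gene}: undeclared species {sname!r}"
                    )

    # -- transforms ----------------------------------------------------
    def copy(self) -> "ModelSpec":
        return ModelSpec(
            species=list(self.species),
            reactions=list(self.reactions),
            transcription_rules=list(self.transcription_rules),
            parameters=dict(self.parameters),
            mode=self.mode,
            binding_rules=self.binding_rules,
            metadata=json.loads(json.dumps(self.metadata)),
        )

    def scaled_rates(self, factor: float) -> "ModelSpec":
        """Multiply every rate constant by ``factor`` (exact time rescaling).

        Rate-dimension parameters (1/h, a.u./h, 1/(a.u.·h)) are scaled;
        concentration-dimension parameters (activation/repression constants,
        names starting with ``K``) are left untouched, so trajectories are
        reproduced exactly on a time axis compressed by ``factor``.
        """
        if factor <= 0:
            raise ConfigurationError("scale factor must be positive")
        new = self.copy()
        new.parameters = {
            k: (v if _is_concentration_param(k) else v * factor)
            for k, v in self.parameters.items()
        }
        new.metadata.setdefault("rate_scalings", []).append(factor)
        return new

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "mode": self.mode,
            "species": [
                {
                    "name": s.name,
                    "compartment": s.compartment,
                    "kind": s.kind,
                    "constituents": list(s.constituents),
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "reactants": [list(x) for x in r.reactants],
                    "products": [list(x) for x in r.products],
                    "rate_param": r.rate_param,
                    "label": r.label,
                }
                for r in self.reactions
            ],
            "transcription_rules": [
                {
                    "gene": t.gene, "mrna": t.mrna, "protein": t.protein,
                    "mode": t.mode, "activator": t.activator,
                    "vmax_param": t.vmax_param, "basal_param": t.basal_param,
                    "k_act_param": t.k_act_param, "repressor": t.repressor,
                    "k_rep_param": t.k_rep_param,
                    "degradation_param": t.degradation_param,
                }
                for t in self.transcription_rules
            ],
            "parameters": dict(self.parameters),
            "metadata": self.metadata,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            species=[
                Species(
                    name=s["name"], compartment=s["compartment"],
                    kind=s["kind"], constituents=tuple(s["constituents"]),
                )
                for s in d["species"]
            ],
            reactions=[
                Reaction(
                    reactants=tuple((n, int(k)) for n, k in r["reactants"]),
                    products=tuple((n, int(k)) for n, k in r["products"]),
                    rate_param=r["rate_param"], label=r.get("label", ""),
                )
                for r in d["reactions"]
            ],
            transcription_rules=[TranscriptionRule(**t) for t in d["transcription_rules"]],
            parameters=dict(d["parameters"]),
            mode=d.get("mode", "reduced"),
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def from_json(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _is_concentration_param(name: str) -> bool:
    # K_* activation/repression constants have concentration units and are
    # invariant under time rescaling
    return name.startswith("K")


# ---------------------------------------------------------------------------
# genetic perturbations
# ---------------------------------------------------------------------------

def apply_perturbation(model: ModelSpec, p: GeneticPerturbation) -> ModelSpec:
    """Return a new ModelSpec with one genetic perturbation applied.

    The input model is never modified.  Knockout/knockdown only rescale the
    gene's transcription parameters (species count unchanged); overexpression
    adds exactly one zeroth-order production reaction for the gene's protein.
    """
    rule = model.transcription_rule(p.gene)
    new = model.copy()
    if p.action == "knockout":
        new.parameters[rule.vmax_param] = 0.0
        if rule.basal_param:
            new.parameters[rule.basal_param] = 0.0
    elif p.action == "knockdown":
        new.parameters[rule.vmax_param] *= p.fraction
        if rule.basal_param:
            new.parameters[rule.basal_param] *= p.fraction
    else:  # overexpress
        rate = p.extra_production
        if rate is None:
            rate = model.parameters.get(f"oe_default_{p.gene}")
            if rate is None:
                raise ConfigurationError(
                    f"no default overexpression rate for {p.gene}; "
                    "give extra_production explicitly"
                )
            p = replace_extra(p, rate)
        pname = f"oe_{p.gene}"
        suffix = 2
        while pname in new.parameters:
            pname = f"oe_{p.gene}_{suffix}"
            suffix += 1
        new.parameters[pname] = float(rate)
        new.reactions = new.reactions + [
            Reaction(reactants=(), products=((rule.protein, 1),),
                     rate_param=pname, label=f"constitutive {p.gene} production")
        ]
    plist = new.metadata.setdefault("perturbations", [])
    plist.append({"gene": p.gene, "action": p.action, "fraction": p.fraction,
                  "extra_production": p.extra_production, "onset_time": p.onset_time,
                  "label": p.label})
    return new


def replace_extra(p: GeneticPerturbation, rate: float) -> GeneticPerturbation:
    return GeneticPerturbation(
        gene=p.gene, action=p.action, fraction=p.fraction,
        extra_production=rate, onset_time=p.onset_time,
    )


def apply_perturbations(model: ModelSpec, perturbations) -> ModelSpec:
    """Apply a list of perturbations left to right."""
    for p in perturbations:
        model = apply_perturbation(model, p)
    return model


def parse_perturbations(spec: str):
    """Parse the perturbation mini-grammar.

    ``"Cry1:ko,Cry2:kd:0.3,Chrono:oe"`` -> three perturbations.  Forms:
    ``gene:ko``, ``gene:kd:<fraction>``, ``gene:oe`` (default rate from the
    parameter set) or ``gene:oe:<rate>``.
    """
    out = []
    spec = spec.strip()
    if not spec:
        return out
    for token in spec.split(","):
        parts = token.strip().split(":")
        if len(parts) < 2:
            raise ConfigurationError(f"malformed perturbation {token!r}")
        gene, action = parts[0], parts[1]
        if action == "ko":
            if len(parts) != 2:
                raise ConfigurationError(f"knockout takes no argument: {token!r}")
            out.append(GeneticPerturbation(gene=gene, action="knockout"))
        elif action == "kd":
            if len(parts) != 3:
                raise ConfigurationError(f"knockdown needs a fraction: {token!r}")
            out.append(GeneticPerturbation(gene=gene, action="knockdown",
                                           fraction=float(parts[2])))
        elif action == "oe":
            rate = float(parts[2]) if len(parts) == 3 else None
            out.append(GeneticPerturbation(gene=gene, action="overexpress",
                                           extra_production=rate))
        else:
            raise ConfigurationError(f"unknown action {action!r} in {token!r}")
    return out
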