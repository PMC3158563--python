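"""Reaction network for TNFα-induced IKK/NF-κB activation in microglia.

The model couples a three-state IKK cycle (native → active → inactive →
native) to the canonical IκBα negative-feedback loop on NF-κB, with a
second, outer feedback loop through the A20 protein.  Two structural
choices distinguish the "new" microglial model from the legacy lineage it
descends from:

* the stimulus-induced degradation of NF-κB-bound IκBα proceeds through a
  four-step chain (phosphorylation → E3-ligase recognition →
  ubiquitination → proteasomal degradation) rather than the classical
  two-step (phosphorylation → degradation) description;
* IKK activation and spontaneous inactivation follow Hill kinetics, and
  A20 feedback acts at two sites (attenuation of activation plus direct
  inactivation of active IKK) instead of inhibiting IKK recycling.

Units are µM and minutes throughout; the TNFα stimulus is a dimensionless
level in [0, 1].  Nuclear species are concentrations per nuclear volume
and all cytoplasm↔nucleus fluxes carry the cytoplasmic:nuclear volume
ratio ``kv`` so that the NF-κB moiety is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Sequence, Tuple

import numpy as np
import sympy as sp

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "ModelVariant",
    "NEW_MODEL",
    "LEGACY_MODEL",
    "ParameterSet",
    "Reaction",
    "ModelSystem",
    "SPECIES",
    "PARAM_NAMES",
    "CYTOPLASMIC",
    "NUCLEAR",
    "DEFAULT_PARAMS",
    "DEFAULT_BOUNDS",
    "hill_rate",
    "nfkb_total",
    "build_model",
    "build_driven_model",
]


class ConfigurationError(ValueError):
    """Raised for unknown structural variant flags."""


class ValidationError(ValueError):
    """Raised when a parameter or state violates its declared invariant."""


# ---------------------------------------------------------------------------
# species and parameters
# ---------------------------------------------------------------------------

SPECIES: Tuple[str, ...] = (
    "IKKn", "IKKa", "IKKi",
    "NFkB", "IkBa", "IkBa_NFkB", "pIkBa_NFkB", "rIkBa_NFkB", "uIkBa_NFkB",
    "NFkBn", "IkBan", "IkBan_NFkBn",
    "tIkBa", "tA20", "A20",
)

NUCLEAR: frozenset = frozenset({"NFkBn", "IkBan", "IkBan_NFkBn"})
CYTOPLASMIC: frozenset = frozenset(s for s in SPECIES) - NUCLEAR

#: NF-κB-containing species (cytoplasmic, nuclear) used by the conservation law.
_NFKB_CYT = ("NFkB", "IkBa_NFkB", "pIkBa_NFkB", "rIkBa_NFkB", "uIkBa_NFkB")
_NFKB_NUC = ("NFkBn", "IkBan_NFkBn")

PARAM_NAMES: Tuple[str, ...] = (
    # upstream IKK cycle
    "ka", "h_a", "km_a", "k_afb", "ki", "h_i", "kmmi", "k_a20i", "kp",
    # IκBα / NF-κB downstream module
    "ka1a", "kc1", "kc2", "kr", "ku", "kd",
    "c1a", "h_t", "k_t", "c3a", "c4a", "c5a", "c6a",
    # A20 expression
    "c1", "c3", "c4", "c5",
    # transport
    "ki1", "ke1", "ki3a", "ke3a", "ke2a",
    # structure
    "kv", "NFkB_tot", "IKK_tot",
)

_HILL_COEFFS = ("h_a", "h_i", "h_t")


@dataclass(frozen=True)
class ModelVariant:
    """Structural flags selecting between the legacy and the new model."""

    degradation_pathway: str = "four_step"   # {two_step | four_step}
    ikk_kinetics: str = "hill"               # {linear | hill}
    a20_feedback: str = "dual_site"          # {recycling_inhibition | dual_site}

    _ALLOWED = {
        "degradation_pathway": {"two_step", "four_step"},
        "ikk_kinetics": {"linear", "hill"},
        "a20_feedback": {"recycling_inhibition", "dual_site"},
    }

    def __post_init__(self) -> None:
        for name, allowed in self._ALLOWED.items():
            value = getattr(self, name)
            if value not in allowed:
                raise ConfigurationError(
                    f"unknown {name} flag {value!r}; expected one of {sorted(allowed)}"
                )


NEW_MODEL = ModelVariant("four_step", "hill", "dual_site")
LEGACY_MODEL = ModelVariant("two_step", "linear", "recycling_inhibition")


@dataclass(frozen=True)
class ParameterSet:
    """Named, bounded rate constants of the network (µM / min units)."""

    values: Mapping[str, float]
    bounds: Mapping[str, Tuple[float, float]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = dict(self.values)
        missing = [n for n in PARAM_NAMES if n not in vals]
        if missing:
            raise ValidationError(f"missing parameters: {missing}")
        unknown = [n for n in vals if n not in PARAM_NAMES]
        if unknown:
            raise ValidationError(f"unknown parameters: {unknown}")
        object.__setattr__(self, "values", vals)
        bounds = dict(self.bounds) if self.bounds is not None else dict(DEFAULT_BOUNDS)
        object.__setattr__(self, "bounds", bounds)
        self.validate()

    def validate(self) -> None:
        for name in PARAM_NAMES:
            v = self.values[name]
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"parameter {name} = {v} must be finite and ≥ 0")
        for name in _HILL_COEFFS:
            if self.values[name] < 1:
                raise ValidationError(f"Hill coefficient {name} must be ≥ 1")
        if self.values["kv"] <= 1:
            raise ValidationError("kv (cytoplasmic:nuclear volume ratio) must be > 1")
        for name in ("NFkB_tot", "IKK_tot"):
            if self.values[name] <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name, (lo, hi) in self.bounds.items():
            v = self.values[name]
            if not (lo <= v <= hi):
                raise ValidationError(
                    f"parameter {name} = {v} outside its bound [{lo}, {hi}]"
                )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in PARAM_NAMES], dtype=float)

    def with_updates(self, **updates: float) -> "ParameterSet":
        vals = dict(self.values)
        vals.update(updates)
        return ParameterSet(vals, self.bounds)

    def scaled(self, name: str, factor: float) -> "ParameterSet":
        """Multiply one parameter by ``factor`` (bounds widened to admit it)."""
        vals = dict(self.values)
        vals[name] = vals[name] * factor
        bounds = dict(self.bounds)
        lo, hi = bounds[name]
        bounds[name] = (min(lo, vals[name]), max(hi, vals[name]))
        return ParameterSet(vals, bounds)


# ---------------------------------------------------------------------------
# nominal parameterization
# ---------------------------------------------------------------------------
# Synthetic stand-in for the study's fitted values: chosen once, within the
# legacy two-feedback lineage's orders of magnitude, to reproduce the
# characteristic microglial dynamics (IKK activity peaking near 5 min and
# falling to ~1/3 of peak by 10 min; nuclear NF-κB rising after a ~5 min
# delay to a first peak near 20 min with a damped second phase near 90 min;
# total IκBα dropping below half its resting level by 20 min).

_DEFAULT_VALUES: Dict[str, float] = {
    # upstream
    "ka": 0.055,     # µM/min  maximal TNF-induced IKK activation rate
    "h_a": 2.0,      # –       activation Hill coefficient
    "km_a": 0.015,    # µM      activation half-saturation in IKKn
    "k_afb": 0.05,    # µM      A20 inhibition constant on activation
    "ki": 0.03,     # µM/min  maximal spontaneous IKK inactivation rate
    "h_i": 4.0,      # –       inactivation Hill coefficient (cooperative)
    "kmmi": 0.03,   # µM      inactivation dissociation constant
    "k_a20i": 2.0,   # 1/(µM·min) direct A20-mediated IKK inactivation
    "kp": 0.02,      # 1/min   inactive→native IKK recycling
    # downstream
    "ka1a": 30.0,    # 1/(µM·min) IκBα·NF-κB association
    "kc1": 24.0,     # 1/(µM·min) IKK phosphorylation of complexed IκBα
    "kc2": 12.0,     # 1/(µM·min) IKK-induced degradation of free IκBα (lumped)
    "kr": 0.3,      # 1/min   E3-ligase recognition of phospho-IκBα
    "ku": 0.3,      # 1/min   polyubiquitination
    "kd": 0.5,       # 1/min   proteasomal degradation, NF-κB release
    "c1a": 0.002,   # µM/min  maximal NF-κB-induced ikba transcription
    "h_t": 1.5,      # –       transcription Hill coefficient (shared)
    "k_t": 0.3,    # µM      transcription threshold in NFkBn (shared)
    "c3a": 0.05,     # 1/min   ikba transcript degradation
    "c4a": 0.5,      # 1/min   IκBα translation
    "c5a": 0.006,    # 1/min   free IκBα basal degradation
    "c6a": 0.004,   # 1/min   complexed IκBα basal degradation
    # A20 expression
    "c1": 0.01,      # µM/min  maximal a20 transcription
    "c3": 0.024,     # 1/min   a20 transcript degradation
    "c4": 0.8,       # 1/min   A20 translation
    "c5": 0.1,       # 1/min   A20 protein degradation
    # transport
    "ki1": 0.6,      # 1/min   NF-κB nuclear import
    "ke1": 0.03,     # 1/min   NF-κB nuclear export
    "ki3a": 0.12,    # 1/min   IκBα nuclear import
    "ke3a": 0.06,    # 1/min   IκBα nuclear export
    "ke2a": 0.6,     # 1/min   nuclear IκBα·NF-κB complex export
    # structure
    "kv": 3.3,       # –       cytoplasmic:nuclear volume ratio
    "NFkB_tot": 0.08,  # µM    total NF-κB moiety
    "IKK_tot": 0.16,    # µM    total IKK pool
}

# Literature-style box constraints: rates may range two decades either side
# of nominal, Hill coefficients within [1, 6], structural constants fixed
# tightly.  The free/fixed partition per fitting stage lives in estimation.
_FIXED_STRUCTURAL = {"kv", "NFkB_tot", "IKK_tot", "h_t", "k_t"}

DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {}
for _name, _v in _DEFAULT_VALUES.items():
    if _name in _HILL_COEFFS and _name != "h_t":
        DEFAULT_BOUNDS[_name] = (1.0, 6.0)
    elif _name in _FIXED_STRUCTURAL:
        DEFAULT_BOUNDS[_name] = (_v, _v)
    else:
        DEFAULT_BOUNDS[_name] = (_v / 100.0, _v * 100.0)

DEFAULT_PARAMS = ParameterSet(_DEFAULT_VALUES)


# ---------------------------------------------------------------------------
# scalar rate laws
# ---------------------------------------------------------------------------

def hill_rate(x: float, vmax: float, km: float, h: float) -> float:
    """Saturating Hill rate ``vmax·x^h/(km^h + x^h)``.

    Monotone non-decreasing in ``x``, bounded by ``vmax``; reduces to the
    Michaelis form for ``h = 1`` and returns exactly ``vmax/2`` at
    ``x = km`` for any ``h``.
    """
    if km <= 0:
        raise ValidationError(f"km must be > 0, got {km}")
    if x < 0 or vmax < 0 or h < 1:
        raise ValidationError("hill_rate requires x ≥ 0, vmax ≥ 0, h ≥ 1")
    if x == 0.0:
        return 0.0
    return float(vmax * x**h / (km**h + x**h))


def nfkb_total(state: Sequence[float], kv: float) -> float:
    """Total NF-κB moiety on the cytoplasmic-concentration scale.

    Nuclear contributions are divided by the volume ratio ``kv``; this
    quantity is a first integral of every model variant.
    """
    if kv <= 0:
        raise ValidationError(f"kv must be > 0, got {kv}")
    x = np.asarray(state, dtype=float)
    idx = {s: i for i, s in enumerate(SPECIES)}
    cyt = sum(x[idx[s]] for s in _NFKB_CYT)
    nuc = sum(x[idx[s]] for s in _NFKB_NUC)
    return float(cyt + nuc / kv)


# ---------------------------------------------------------------------------
# symbolic network construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """One reaction: a named rate law plus integer stoichiometry.

    ``rate`` is a sympy expression on the concentration scale of the
    source compartment; the amount flux is ``rate × V(compartment)`` with
    V(cytoplasm) = kv and V(nucleus) = 1.
    """

    name: str
    rate: sp.Expr
    stoich: Mapping[str, int]
    compartment: str = "cytoplasm"


def _sym(name: str) -> sp.Symbol:
    return sp.Symbol(name, nonnegative=True)


def _hill_expr(x: sp.Expr, vmax: sp.Expr, km: sp.Expr, h: sp.Expr) -> sp.Expr:
    return vmax * x**h / (km**h + x**h)


def _reactions(variant: ModelVariant) -> List[Reaction]:
    s = {name: _sym(name) for name in SPECIES}
    p = {name: _sym(name) for name in PARAM_NAMES}
    u = _sym("TNF")

    rx: List[Reaction] = []

    def add(name, rate, stoich, compartment="cytoplasm"):
        rx.append(Reaction(name, sp.sympify(rate), dict(stoich), compartment))

    # --- upstream IKK cycle -------------------------------------------------
    if variant.ikk_kinetics == "hill":
        act = u * _hill_expr(s["IKKn"], p["ka"], p["km_a"], p["h_a"])
        inact = _hill_expr(s["IKKa"], p["ki"], p["kmmi"], p["h_i"])
    else:
        act = u * p["ka"] * s["IKKn"]
        inact = p["ki"] * s["IKKa"]
    if variant.a20_feedback == "dual_site":
        act = act * p["k_afb"] / (p["k_afb"] + s["A20"])
        recycle = p["kp"] * s["IKKi"]
        add("ikk_inactivation_by_a20", p["k_a20i"] * s["A20"] * s["IKKa"],
            {"IKKa": -1, "IKKi": +1})
    else:
        recycle = p["kp"] * s["IKKi"] * p["k_afb"] / (p["k_afb"] + s["A20"])
    add("ikk_activation", act, {"IKKn": -1, "IKKa": +1})
    add("ikk_inactivation", inact, {"IKKa": -1, "IKKi": +1})
    add("ikk_recycling", recycle, {"IKKi": -1, "IKKn": +1})

    # --- IκBα degradation chain --------------------------------------------
    add("nfkb_ikba_association", p["ka1a"] * s["NFkB"] * s["IkBa"],
        {"NFkB": -1, "IkBa": -1, "IkBa_NFkB": +1})
    add("ikba_complex_phosphorylation", p["kc1"] * s["IKKa"] * s["IkBa_NFkB"],
        {"IkBa_NFkB": -1, "pIkBa_NFkB": +1})
    add("free_ikba_inducible_degradation", p["kc2"] * s["IKKa"] * s["IkBa"],
        {"IkBa": -1})
    if variant.degradation_pathway == "four_step":
        add("e3_recognition", p["kr"] * s["pIkBa_NFkB"],
            {"pIkBa_NFkB": -1, "rIkBa_NFkB": +1})
        add("ubiquitination", p["ku"] * s["rIkBa_NFkB"],
            {"rIkBa_NFkB": -1, "uIkBa_NFkB": +1})
        add("proteasomal_degradation", p["kd"] * s["uIkBa_NFkB"],
            {"uIkBa_NFkB": -1, "NFkB": +1})
    else:
        add("proteasomal_degradation", p["kd"] * s["pIkBa_NFkB"],
            {"pIkBa_NFkB": -1, "NFkB": +1})
    add("free_ikba_basal_degradation", p["c5a"] * s["IkBa"], {"IkBa": -1})
    add("complexed_ikba_basal_degradation", p["c6a"] * s["IkBa_NFkB"],
        {"IkBa_NFkB": -1, "NFkB": +1})

    # --- inducible gene expression (zero constitutive terms) ----------------
    tx = _hill_expr(s["NFkBn"], sp.Integer(1), p["k_t"], p["h_t"])
    add("ikba_transcription", p["c1a"] * tx, {"tIkBa": +1})
    add("ikba_transcript_degradation", p["c3a"] * s["tIkBa"], {"tIkBa": -1})
    add("ikba_translation", p["c4a"] * s["tIkBa"], {"IkBa": +1})
    add("a20_transcription", p["c1"] * tx, {"tA20": +1})
    add("a20_transcript_degradation", p["c3"] * s["tA20"], {"tA20": -1})
    add("a20_translation", p["c4"] * s["tA20"], {"A20": +1})
    add("a20_degradation", p["c5"] * s["A20"], {"A20": -1})

    # --- nucleocytoplasmic transport ---------------------------------------
    add("nfkb_nuclear_import", p["ki1"] * s["NFkB"], {"NFkB": -1, "NFkBn": +1})
    add("nfkb_nuclear_export", p["ke1"] * s["NFkBn"],
        {"NFkBn": -1, "NFkB": +1}, compartment="nucleus")
    add("ikba_nuclear_import", p["ki3a"] * s["IkBa"], {"IkBa": -1, "IkBan": +1})
    add("ikba_nuclear_export", p["ke3a"] * s["IkBan"],
        {"IkBan": -1, "IkBa": +1}, compartment="nucleus")
    add("nuclear_association", p["ka1a"] * s["NFkBn"] * s["IkBan"],
        {"NFkBn": -1, "IkBan": -1, "IkBan_NFkBn": +1}, compartment="nucleus")
    add("nuclear_complex_export", p["ke2a"] * s["IkBan_NFkBn"],
        {"IkBan_NFkBn": -1, "IkBa_NFkB": +1}, compartment="nucleus")

    return rx


def _derivatives(reactions: Sequence[Reaction],
                 species: Sequence[str]) -> List[sp.Expr]:
    """Concentration ODE right-hand sides from the reaction list.

    d[s]/dt = Σ_r ν_{r,s} · w_r · V(source) / V(s), with V(cyt)=kv, V(nuc)=1.
    """
    kv = _sym("kv")
    vol = {name: (sp.Integer(1) if name in NUCLEAR else kv) for name in SPECIES}
    dx = {name: sp.Integer(0) for name in species}
    for r in reactions:
        v_src = sp.Integer(1) if r.compartment == "nucleus" else kv
        for sp_name, nu in r.stoich.items():
            if sp_name in dx:
                dx[sp_name] = dx[sp_name] + nu * r.rate * v_src / vol[sp_name]
    return [sp.together(dx[name]) for name in species]


def _compile(exprs: Sequence[sp.Expr], species: Sequence[str],
             extra_inputs: Sequence[str]) -> Tuple[Callable, Callable]:
    """Lambdify the RHS vector and its state Jacobian.

    Returns ``(f, jac)`` with signatures ``f(x, *inputs, p)`` and
    ``jac(x, *inputs, p)`` where ``x`` and ``p`` are flat arrays.
    """
    x_vec = sp.DeferredVector("x")
    p_vec = sp.DeferredVector("p")
    sub = {_sym(name): x_vec[i] for i, name in enumerate(species)}
    sub.update({_sym(name): p_vec[j] for j, name in enumerate(PARAM_NAMES)})
    inputs = [_sym(name) for name in extra_inputs]

    mat = sp.Matrix(exprs)
    jac_mat = mat.jacobian([_sym(name) for name in species])
    mat_s = mat.subs(sub)
    jac_s = jac_mat.subs(sub)
    args = (x_vec, *inputs, p_vec)
    f = sp.lambdify(args, sp.flatten(mat_s), modules="numpy", cse=True)
    jac = sp.lambdify(args, jac_s, modules="numpy", cse=True)
    return f, jac


@dataclass
class ModelSystem:
    """A compiled reaction network ready for integration.

    ``rhs(t, x, stimulus)`` evaluates the derivative vector given a
    stimulus function TNF(t); ``jacobian`` is the analytic state Jacobian
    used by the stiff integrators.  ``driven`` names a species whose
    dynamics are replaced by an external input (loop breaking); its value
    is then supplied by the caller instead of an ODE.
    """

    variant: ModelVariant
    params: ParameterSet
    species: Tuple[str, ...]
    reactions: List[Reaction]
    driven: str | None = None
    _f: Callable = field(repr=False, default=None)  # type: ignore[assignment]
    _jac: Callable = field(repr=False, default=None)  # type: ignore[assignment]
    _dexprs: List[sp.Expr] = field(repr=False, default_factory=list)

    @property
    def index(self) -> Dict[str, int]:
        return {name: i for i, name in enumerate(self.species)}

    def with_params(self, params: ParameterSet) -> "ModelSystem":
        system = replace(self, params=params)
        system.__dict__.pop("_p_cache", None)
        return system

    @property
    def _p(self) -> np.ndarray:
        # parameter vector cached per instance: rhs is called thousands of
        # times per integration
        cache = self.__dict__.get("_p_cache")
        if cache is None:
            cache = self.params.as_array()
            self.__dict__["_p_cache"] = cache
        return cache

    # Solvers may probe marginally negative concentrations, and fractional
    # Hill exponents make x**h (rhs) and x**(h-1) (Jacobian) undefined
    # there, so states are clipped: at 0 for rates, at a tiny positive
    # floor for the Jacobian where inverse powers of x can appear.

    # -- full model interface ------------------------------------------------
    def rhs(self, t: float, x: np.ndarray,
            stimulus: Callable[[float], float]) -> np.ndarray:
        xq = np.maximum(np.asarray(x, dtype=float), 0.0)
        return np.asarray(self._f(xq, float(stimulus(t)), self._p), dtype=float)

    def jacobian(self, t: float, x: np.ndarray,
                 stimulus: Callable[[float], float]) -> np.ndarray:
        xq = np.maximum(np.asarray(x, dtype=float), 1e-30)
        return np.asarray(self._jac(xq, float(stimulus(t)), self._p), dtype=float)

    # -- driven (loop-broken) interface --------------------------------------
    def rhs_driven(self, t: float, x: np.ndarray,
                   stimulus: Callable[[float], float],
                   drive: Callable[[float], float]) -> np.ndarray:
        xq = np.maximum(np.asarray(x, dtype=float), 0.0)
        return np.asarray(
            self._f(xq, float(stimulus(t)), float(drive(t)), self._p), dtype=float)

    def jacobian_driven(self, t: float, x: np.ndarray,
                        stimulus: Callable[[float], float],
                        drive: Callable[[float], float]) -> np.ndarray:
        xq = np.maximum(np.asarray(x, dtype=float), 1e-30)
        return np.asarray(
            self._jac(xq, float(stimulus(t)), float(drive(t)), self._p), dtype=float)

    def derivative_exprs(self) -> List[sp.Expr]:
        """Symbolic RHS in the named species/parameter symbols."""
        return list(self._dexprs)


def build_model(variant: ModelVariant, params: ParameterSet) -> ModelSystem:
    """Compile the full 15-species network for one structural variant."""
    if not isinstance(variant, ModelVariant):
        raise ConfigurationError(f"expected ModelVariant, got {variant!r}")
    params.validate()
    rx = _reactions(variant)
    exprs = _derivatives(rx, SPECIES)
    f, jac = _compile(exprs, SPECIES, ["TNF"])
    return ModelSystem(variant, params, SPECIES, rx,
                       _f=f, _jac=jac, _dexprs=exprs)


_DRIVEN_LAYOUT = {
    # loop-broken downstream module: IKKa is the input, IKK cycle removed.
    "IKKa": tuple(s for s in SPECIES if s not in ("IKKn", "IKKa", "IKKi")),
    # loop-broken upstream module: nuclear NF-κB is the input.
    "NFkBn": ("IKKn", "IKKa", "IKKi", "tA20", "A20"),
}


def build_driven_model(variant: ModelVariant, params: ParameterSet,
                       driven: str) -> ModelSystem:
    """Compile a loop-broken submodule with ``driven`` supplied externally.

    ``driven = "IKKa"`` yields the downstream IκBα/NF-κB module (12
    species); ``driven = "NFkBn"`` yields the upstream IKK/A20 module (5
    species).  Reactions that only touch removed species are dropped; the
    driven species appears in the surviving rate laws as an input.
    """
    if driven not in _DRIVEN_LAYOUT:
        raise ConfigurationError(
            f"driven species must be one of {sorted(_DRIVEN_LAYOUT)}, got {driven!r}")
    params.validate()
    keep = _DRIVEN_LAYOUT[driven]
    rx = _reactions(variant)
    kept_rx = [r for r in rx if any(s in keep for s in r.stoich)]
    exprs = _derivatives(kept_rx, keep)
    f, jac = _compile(exprs, keep, ["TNF", driven])
    return ModelSystem(variant, params, tuple(keep), kept_rx, driven=driven,
                       _f=f, _jac=jac, _dexprs=exprs)
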