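"""Construction of the bilateral Mauthner escape circuit.

The full circuit contains, per side, one Mauthner cell (LIF), a pool of 30
feedforward glycinergic interneurons (LIF) and 30 VIIIth-ganglion auditory
afferents (HH) whose membrane areas span 2000-20000 um^2 so that stronger
stimuli recruit more of them.  Each afferent is paired one-to-one with an FF
interneuron ('one functional unit').  Connectivity per side:

* FF -> ipsilateral M: glycine, 25 nS, 0.3 ms delay (all-to-one)
* FF -> contralateral M: glycine, 2.5 x the ipsilateral level (all-to-one)
* afferents -> ipsilateral M: gap junction 15 nS (0.4 ms dendritic low-pass)
  plus glutamate 12 nS with 0.7 ms delay (all-to-one)
* afferents -> ipsilateral FF: gap junction 10 nS (one-to-one)
* FF -> contralateral FF: glycine 12 nS, 0.3 ms delay (all-to-all)

Circuit variants enable/disable the crossed FF->M and FF->FF groups to
reproduce the configurations compared in the study; in-silico ablations
remove cells and every connection touching them.
"""

from __future__ import annotations

import copy
import enum
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import AblationError, ConfigurationError
from .neurodynamics import GapJunctionSpec, HHParams, LIFParams, SynapseSpec

__all__ = [
    "CircuitVariant",
    "AblationSpec",
    "PopulationSpec",
    "CircuitSpec",
    "build_circuit",
    "mirror_check",
    "default_config",
    "load_config",
    "FULL_CIRCUIT",
]

_SIDES = ("left", "right")
_OTHER = {"left": "right", "right": "left"}


class CircuitVariant(enum.Enum):
    """Connectivity variants of the feedforward-inhibition motif.

    ``BIASED_BILATERAL_MUTUAL`` (biased crossed M-cell inhibition plus mutual
    FF-FF inhibition) is the experimentally supported full circuit.
    """

    IPSI_ONLY = "ipsi_only"
    SYM_BILATERAL = "sym_bilateral"
    BIASED_BILATERAL = "biased_bilateral"
    SYM_BILATERAL_MUTUAL = "sym_bilateral_mutual"
    BIASED_BILATERAL_MUTUAL = "biased_bilateral_mutual"
    CONTRA_ONLY_WEAK = "contra_only_weak"
    CONTRA_ONLY_STRONG = "contra_only_strong"


#: Alias for the experimentally supported configuration.
FULL_CIRCUIT = CircuitVariant.BIASED_BILATERAL_MUTUAL

_HAS_IPSI_M = {v: v not in (CircuitVariant.CONTRA_ONLY_WEAK,
                            CircuitVariant.CONTRA_ONLY_STRONG)
               for v in CircuitVariant}
_HAS_MUTUAL = {v: v in (CircuitVariant.SYM_BILATERAL_MUTUAL,
                        CircuitVariant.BIASED_BILATERAL_MUTUAL)
               for v in CircuitVariant}


@dataclass(frozen=True)
class AblationSpec:
    """Removal of cells (and all their connections) from one side.

    ``fraction='half'`` removes ceil(n/2) cells; by default the cells at even
    positions within the pool, spreading the removal across the
    recruitment-ordered afferent/FF pairs.  ``method='random'`` with a seed
    removes a random subset instead (sensitivity checks).
    """

    target: str  # 'FF_pool' | 'Mauthner'
    side: str  # 'left' | 'right'
    fraction: str = "all"  # 'all' | 'half'
    method: str = "even"  # 'even' | 'random'
    seed: int | None = None

    def __post_init__(self):
        if self.target not in ("FF_pool", "Mauthner"):
            raise ConfigurationError(f"unknown ablation target {self.target!r}")
        if self.side not in _SIDES:
            raise ConfigurationError(f"unknown side {self.side!r}")
        if self.fraction not in ("all", "half"):
            raise ConfigurationError(f"unknown fraction {self.fraction!r}")
        if self.method not in ("even", "random"):
            raise ConfigurationError(f"unknown method {self.method!r}")

    @property
    def population(self) -> str:
        return "FF" if self.target == "FF_pool" else "M"


@dataclass(frozen=True)
class PopulationSpec:
    """One population on one side; ``cell_ids`` are the surviving cells."""

    name: str
    side: str
    kind: str  # 'lif' | 'hh'
    params: LIFParams | HHParams
    cell_ids: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.cell_ids)


@dataclass(frozen=True)
class CircuitSpec:
    """Fully resolved parameterization of one circuit build."""

    populations: dict[tuple[str, str], PopulationSpec]
    synapses: tuple[SynapseSpec, ...]
    gap_junctions: tuple[GapJunctionSpec, ...]
    variant: CircuitVariant
    ablations: tuple[AblationSpec, ...] = ()
    config: dict = field(default_factory=dict, compare=False)

    @property
    def dt(self) -> float:
        return self.config.get("sim", {}).get("dt", 0.01)

    # -- lookup helpers --------------------------------------------------

    def group(self, name: str) -> SynapseSpec | GapJunctionSpec:
        for g in (*self.synapses, *self.gap_junctions):
            if g.name == name:
                return g
        raise ConfigurationError(f"unknown group {name!r}")

    def group_names(self) -> list[str]:
        return [g.name for g in (*self.synapses, *self.gap_junctions)]

    def population(self, name: str, side: str) -> PopulationSpec:
        try:
            return self.populations[(name, side)]
        except KeyError:
            raise ConfigurationError(f"unknown population ({name}, {side})")

    # -- transformations -------------------------------------------------

    def with_zeroed_groups(self, names) -> "CircuitSpec":
        """Copy with the named synapse/gap conductances set to zero.

        Zeroing a gap junction also removes its standing conductance load on
        the postsynaptic cell, so this isolates cells for calibration
        protocols.
        """
        names = set(names)
        unknown = names - set(self.group_names())
        if unknown:
            raise ConfigurationError(f"unknown group(s): {sorted(unknown)}")
        syns = tuple(replace(s, g_peak=0.0) if s.name in names else s
                     for s in self.synapses)
        gaps = tuple(replace(g, g_gap=0.0) if g.name in names else g
                     for g in self.gap_junctions)
        return replace(self, synapses=syns, gap_junctions=gaps)

    def isolated(self, keep_groups=()) -> "CircuitSpec":
        """Copy with every coupling zeroed except ``keep_groups``."""
        keep = set(keep_groups)
        return self.with_zeroed_groups(
            [n for n in self.group_names() if n not in keep])

    def mirrored(self) -> "CircuitSpec":
        """The left/right label swap of this circuit."""

        def flip_pop(key):
            return (key[0], _OTHER[key[1]])

        pops = {}
        for key, pop in self.populations.items():
            pops[flip_pop(key)] = replace(pop, side=_OTHER[pop.side])
        syns = tuple(
            replace(s, name=_group_name(flip_pop(s.pre_pop),
                                        flip_pop(s.post_pop), s.transmitter),
                    pre_pop=flip_pop(s.pre_pop), post_pop=flip_pop(s.post_pop),
                    laterality=s.laterality)
            for s in self.synapses)
        gaps = tuple(
            replace(g, name=_group_name(flip_pop(g.pre_pop),
                                        flip_pop(g.post_pop), "gap"),
                    pre_pop=flip_pop(g.pre_pop), post_pop=flip_pop(g.post_pop))
            for g in self.gap_junctions)
        abls = tuple(replace(a, side=_OTHER[a.side]) for a in self.ablations)
        return replace(self, populations=pops, synapses=syns,
                       gap_junctions=gaps, ablations=abls)

    def canonical(self):
        """Order-independent plain representation (for equality checks)."""
        pops = sorted(
            (k[0], k[1], p.kind, p.cell_ids, repr(p.params))
            for k, p in self.populations.items())
        syns = sorted(
            (s.pre_pop, s.post_pop, s.transmitter, s.g_peak, s.delay,
             s.tau_decay, s.E_rev, s.pattern)
            for s in self.synapses)
        gaps = sorted(
            (g.pre_pop, g.post_pop, g.g_gap, g.pattern, g.dendritic_tau,
             g.lumped)
            for g in self.gap_junctions)
        return (pops, syns, gaps)

    # -- reporting / IO --------------------------------------------------

    def connectivity_table(self):
        """Resolved connectivity as a tidy DataFrame (compare against the
        parameter table the circuit was built from)."""
        import pandas as pd

        rows = []
        for s in self.synapses:
            rows.append({
                "group": s.name, "kind": s.transmitter,
                "pre": f"{s.pre_pop[0]}.{s.pre_pop[1]}",
                "post": f"{s.post_pop[0]}.{s.post_pop[1]}",
                "conductance_nS": s.g_peak, "delay_ms": s.delay,
                "tau_ms": s.tau_decay, "E_rev_mV": s.E_rev,
                "pattern": s.pattern})
        for g in self.gap_junctions:
            rows.append({
                "group": g.name, "kind": "gap",
                "pre": f"{g.pre_pop[0]}.{g.pre_pop[1]}",
                "post": f"{g.post_pop[0]}.{g.post_pop[1]}",
                "conductance_nS": g.g_gap, "delay_ms": np.nan,
                "tau_ms": g.dendritic_tau, "E_rev_mV": np.nan,
                "pattern": g.pattern})
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        doc = {
            "variant": self.variant.value,
            "ablations": [
                {"target": a.target, "side": a.side, "fraction": a.fraction,
                 "method": a.method, "seed": a.seed}
                for a in self.ablations],
            "config": self.config,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @staticmethod
    def load(path) -> "CircuitSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        abls = [AblationSpec(**a) for a in doc.get("ablations", [])]
        return build_circuit(CircuitVariant(doc["variant"]), ablations=abls,
                             config=doc["config"])


# ---------------------------------------------------------------------------
# default configuration
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "lif": {
        "M": {"Rm": 10.0, "Erest": -79.0, "ECl": -75.0, "Espike": -61.0,
              "tau_m": 23.0, "t_refractory": 2.0, "n_per_side": 1},
        "FF": {"Rm": 400.0, "Erest": -77.0, "ECl": -75.0, "Espike": -61.0,
               "tau_m": 10.0, "t_refractory": 2.0, "n_per_side": 30},
    },
    "hh": {
        "auditory": {"El": -79.0, "EK": -90.0, "ENa": 50.0, "gl": 0.05,
                     "gNa": 100.0, "gK": 200.0, "n_per_side": 30,
                     "area_min": 2000.0, "area_max": 20000.0,
                     "v_rest_target": -79.0},
    },
    "synapses": {
        "ff_ipsi_m": {"g_peak": 25.0, "delay": 0.3, "tau_decay": 2.0},
        "ff_contra_m_ratio": 2.5,  # contra strength as a multiple of ipsi
        "ff_contra_ff": {"g_peak": 12.0, "delay": 0.3, "tau_decay": 2.0},
        "aud_m_glut": {"g_peak": 12.0, "delay": 0.7, "tau_decay": 2.0},
    },
    "gaps": {
        # aud_m is the compound electrical conductance of the whole afferent
        # pool onto one M-cell (lumped), keeping the M-cell's in-circuit
        # input resistance near its measured value; aud_ff is per pair.
        "aud_m": {"g_gap": 15.0, "dendritic_tau": 0.4, "lumped": True},
        "aud_ff": {"g_gap": 10.0},
    },
    "sim": {"dt": 0.01, "glutamate_E_rev": 0.0},
}


def default_config() -> dict:
    """A deep copy of the default (parameter-table) configuration."""
    return copy.deepcopy(_DEFAULT_CONFIG)


def load_config(path=None) -> dict:
    """Load a hierarchical YAML config; ``None`` returns the defaults."""
    if path is None:
        return default_config()
    with open(path) as fh:
        return yaml.safe_load(fh)


def _merge(base: dict, overrides: dict, path="") -> dict:
    """Deep merge ``overrides`` into ``base``; unknown keys are errors."""
    out = dict(base)
    for k, v in overrides.items():
        if k not in base:
            raise ConfigurationError(f"unknown configuration key {path + k!r}")
        if isinstance(base[k], dict):
            if not isinstance(v, dict):
                raise ConfigurationError(
                    f"configuration key {path + k!r} expects a mapping")
            out[k] = _merge(base[k], v, path + k + ".")
        else:
            out[k] = v
    return out


def _group_name(pre: tuple[str, str], post: tuple[str, str],
                label: str) -> str:
    return f"{pre[0]}.{pre[1]}->{post[0]}.{post[1]}:{label}"


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def build_circuit(
    variant: CircuitVariant = FULL_CIRCUIT,
    ablations=(),
    overrides: dict | None = None,
    group_overrides: dict | None = None,
    config: dict | None = None,
) -> CircuitSpec:
    """Build a fully resolved :class:`CircuitSpec`.

    ``overrides`` deep-merges into the default configuration (unknown keys
    are configuration errors); ``group_overrides`` maps built group names to
    field replacements (e.g. ``{"FF.left->M.left:glycine": {"g_peak": 30}}``)
    and is applied after construction, so one-sided overrides break mirror
    symmetry as expected.  Ablations are applied in order; ablating an
    already-empty population, or repeating an identical ablation, errors.
    """
    if not isinstance(variant, CircuitVariant):
        try:
            variant = CircuitVariant(variant)
        except ValueError:
            raise ConfigurationError(f"unknown circuit variant {variant!r}")
    cfg = config if config is not None else default_config()
    if overrides:
        cfg = _merge(cfg, overrides)

    m_cfg = dict(cfg["lif"]["M"])
    ff_cfg = dict(cfg["lif"]["FF"])
    n_m = int(m_cfg.pop("n_per_side"))
    n_ff = int(ff_cfg.pop("n_per_side"))
    m_params = LIFParams(**m_cfg)
    ff_params = LIFParams(**ff_cfg)

    hh_cfg = dict(cfg["hh"]["auditory"])
    n_aud = int(hh_cfg.pop("n_per_side"))
    areas = np.linspace(hh_cfg.pop("area_min"), hh_cfg.pop("area_max"), n_aud)
    hh_params = HHParams(surface_areas=tuple(areas), **hh_cfg)

    populations: dict[tuple[str, str], PopulationSpec] = {}
    for side in _SIDES:
        populations[("M", side)] = PopulationSpec(
            "M", side, "lif", m_params, tuple(range(n_m)))
        populations[("FF", side)] = PopulationSpec(
            "FF", side, "lif", ff_params, tuple(range(n_ff)))
        populations[("auditory", side)] = PopulationSpec(
            "auditory", side, "hh", hh_params, tuple(range(n_aud)))

    scfg = cfg["synapses"]
    gcfg = cfg["gaps"]
    E_glut = cfg["sim"]["glutamate_E_rev"]
    ipsi = scfg["ff_ipsi_m"]
    ratio = scfg["ff_contra_m_ratio"]
    contra_strong = ipsi["g_peak"] * ratio
    contra_by_variant = {
        CircuitVariant.IPSI_ONLY: None,
        CircuitVariant.SYM_BILATERAL: ipsi["g_peak"],
        CircuitVariant.BIASED_BILATERAL: contra_strong,
        CircuitVariant.SYM_BILATERAL_MUTUAL: ipsi["g_peak"],
        CircuitVariant.BIASED_BILATERAL_MUTUAL: contra_strong,
        CircuitVariant.CONTRA_ONLY_WEAK: ipsi["g_peak"],
        CircuitVariant.CONTRA_ONLY_STRONG: contra_strong,
    }

    synapses: list[SynapseSpec] = []
    gaps: list[GapJunctionSpec] = []
    for side in _SIDES:
        other = _OTHER[side]
        if _HAS_IPSI_M[variant]:
            synapses.append(SynapseSpec(
                _group_name(("FF", side), ("M", side), "glycine"),
                ("FF", side), ("M", side), "glycine", ipsi["g_peak"],
                ipsi["delay"], ipsi["tau_decay"], m_params.ECl,
                "all_to_one", "ipsilateral"))
        g_contra = contra_by_variant[variant]
        if g_contra is not None:
            synapses.append(SynapseSpec(
                _group_name(("FF", side), ("M", other), "glycine"),
                ("FF", side), ("M", other), "glycine", g_contra,
                ipsi["delay"], ipsi["tau_decay"], m_params.ECl,
                "all_to_one", "contralateral"))
        if _HAS_MUTUAL[variant]:
            ffff = scfg["ff_contra_ff"]
            synapses.append(SynapseSpec(
                _group_name(("FF", side), ("FF", other), "glycine"),
                ("FF", side), ("FF", other), "glycine", ffff["g_peak"],
                ffff["delay"], ffff["tau_decay"], ff_params.ECl,
                "all_to_all", "contralateral"))
        glut = scfg["aud_m_glut"]
        synapses.append(SynapseSpec(
            _group_name(("auditory", side), ("M", side), "glutamate"),
            ("auditory", side), ("M", side), "glutamate", glut["g_peak"],
            glut["delay"], glut["tau_decay"], E_glut,
            "all_to_one", "ipsilateral"))
        gaps.append(GapJunctionSpec(
            _group_name(("auditory", side), ("M", side), "gap"),
            ("auditory", side), ("M", side), gcfg["aud_m"]["g_gap"],
            "all_to_one", gcfg["aud_m"]["dendritic_tau"],
            lumped=gcfg["aud_m"].get("lumped", False)))
        gaps.append(GapJunctionSpec(
            _group_name(("auditory", side), ("FF", side), "gap"),
            ("auditory", side), ("FF", side), gcfg["aud_ff"]["g_gap"],
            "one_to_one", None,
            lumped=gcfg["aud_ff"].get("lumped", False)))

    if group_overrides:
        by_name = {s.name: s for s in synapses}
        by_name.update({g.name: g for g in gaps})
        unknown = set(group_overrides) - set(by_name)
        if unknown:
            raise ConfigurationError(
                f"group override(s) reference unknown group(s): "
                f"{sorted(unknown)}")
        synapses = [replace(s, **group_overrides.get(s.name, {}))
                    for s in synapses]
        gaps = [replace(g, **group_overrides.get(g.name, {})) for g in gaps]

    def alive(ref: tuple[str, str]) -> bool:
        p = populations.get(ref)
        return p is not None and p.n > 0

    circuit = CircuitSpec(
        populations=populations,
        synapses=tuple(s for s in synapses
                       if alive(s.pre_pop) and alive(s.post_pop)),
        gap_junctions=tuple(g for g in gaps
                            if alive(g.pre_pop) and alive(g.post_pop)),
        variant=variant, ablations=(), config=cfg)
    for abl in ablations:
        circuit = _apply_ablation(circuit, abl)
    return circuit


def _apply_ablation(circuit: CircuitSpec, abl: AblationSpec) -> CircuitSpec:
    if abl in circuit.ablations:
        raise AblationError(f"ablation {abl} already applied")
    key = (abl.population, abl.side)
    pop = circuit.populations.get(key)
    if pop is None or pop.n == 0:
        raise AblationError(f"population {key} is absent or already empty")
    ids = list(pop.cell_ids)
    if abl.fraction == "all":
        removed = set(ids)
    else:
        n_remove = -(-len(ids) // 2)  # ceil(n/2)
        if abl.method == "even":
            removed = set(ids[0::2][:n_remove])
        else:
            rng = np.random.default_rng(abl.seed)
            removed = set(rng.choice(ids, size=n_remove, replace=False).tolist())
    survivors = tuple(i for i in ids if i not in removed)
    pops = dict(circuit.populations)
    pops[key] = replace(pop, cell_ids=survivors)

    def alive(ref: tuple[str, str]) -> bool:
        p = pops.get(ref)
        return p is not None and p.n > 0

    syns = tuple(s for s in circuit.synapses
                 if alive(s.pre_pop) and alive(s.post_pop))
    gaps = tuple(g for g in circuit.gap_junctions
                 if alive(g.pre_pop) and alive(g.post_pop))
    return replace(circuit, populations=pops, synapses=syns,
                   gap_junctions=gaps,
                   ablations=circuit.ablations + (abl,))


def mirror_check(circuit: CircuitSpec) -> bool:
    """True iff swapping left/right labels leaves the circuit unchanged."""
    return circuit.canonical() == circuit.mirrored().canonical()
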