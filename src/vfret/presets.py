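"""Kinetic presets: one named parameter set per experimental condition.

A :class:`KineticPreset` bundles everything the trajectory sampler needs to
emulate one condition of the vectorial-folding experiments: the construct
(number of TTAGGG repeats, or c-Myc / poly-T controls), the folding mode
(post-folding ``pf``, helicase-driven ``vf_repx``, exonuclease-driven
``vf_exo``, or LiCl-to-KCl ``salt_exchange``), ATP concentration, per-state
FRET levels, pathway probabilities and ligand-capture parameters.

The full registry of named presets mirroring the study's condition matrix is
built by :func:`builtin_presets` and can be exported to / loaded from a
human-readable YAML file.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import yaml

MODES = ("pf", "vf_repx", "vf_exo", "salt_exchange")
SALTS = ("KCl", "NaCl", "LiCl")
LIGANDS = ("none", "C2", "POT1")

#: folding rate shared by all constructs: 1 / 0.41 s (one-step folding dwell)
K_FOLD_DEFAULT = 1.0 / 0.41

#: ATP dependence of the Rep-X per-nucleotide release rate (Hill form).
#: Anchored so that 50 uM ATP gives exactly 1.0 nt/s (telomerase speed) while
#: saturating ATP (1 mM) unwinds in well under one 100 ms frame.
ATP_HILL = 2.0
ATP_KHALF_UM = 2000.0
ATP_KCAT = (ATP_KHALF_UM**ATP_HILL + 50.0**ATP_HILL) / 50.0**ATP_HILL  # = 1601.0


def atp_release_rate(atp_uM: float, k_cat: float = ATP_KCAT,
                     k_half: float = ATP_KHALF_UM, hill: float = ATP_HILL) -> float:
    """Per-nucleotide strand-release rate (s^-1) at a given ATP concentration."""
    if atp_uM <= 0:
        return 0.0
    s = float(atp_uM) ** hill
    return k_cat * s / (k_half**hill + s)


@dataclass
class Ligand:
    """Overhang-capturing ligand (complementary C-strand or POT1)."""

    name: str = "none"                # one of LIGANDS
    conc_nM: float = 0.0
    k_on: float = 0.0                 # nM^-1 s^-1
    accessible_fraction: float = 0.0  # plateau of the bound fraction

    def __post_init__(self):
        if self.name not in LIGANDS:
            raise ValueError(f"unknown ligand {self.name!r}")
        if not 0.0 <= self.accessible_fraction <= 1.0:
            raise ValueError("accessible_fraction must lie in [0, 1]")

    @property
    def rate(self) -> float:
        """Pseudo-first-order capture rate k_on * [ligand] (s^-1)."""
        return self.k_on * self.conc_nM


@dataclass
class KineticPreset:
    """One experimental condition of the vectorial-folding assay."""

    name: str
    construct: str                    # G2..G8, cMyc, mutant-*, polyT
    n_repeats: int
    overhang_len_nt: int
    mode: str                         # pf | vf_repx | vf_exo | salt_exchange
    salt: str = "KCl"
    atp_uM: float = 1000.0
    k_cat_unwind: float = ATP_KCAT    # per-nt max release rate (s^-1)
    Km_atp: float = ATP_KHALF_UM      # half-saturation ATP (uM)
    atp_hill: float = ATP_HILL
    k_exo_nt: float = 12.0            # ATP-independent per-nt digestion rate
    k_fold: float = K_FOLD_DEFAULT
    p_multistep: float = 0.0
    k_intermediate: float = 0.2       # exit rate from the intermediate (s^-1)
    conformers: tuple = ((0.75, 1.0),)          # (FRET mean, weight)
    conformers_onestep: Optional[tuple] = None   # pathway-specific weights
    conformers_multistep: Optional[tuple] = None
    E_duplex: float = 0.50
    E_ss: float = 0.60
    E_intermediate: float = 0.65
    E_bound: float = 0.30
    ligand: Ligand = field(default_factory=Ligand)
    k_relax: float = 0.0              # vf->pf conformer re-draw rate (s^-1)
    relax_weights: Optional[tuple] = None  # weights used on re-draw (pf set)
    t_enzyme_arrival: float = 10.0    # s (also the salt-exchange time)
    arrival_jitter_s: float = 4.2     # per-molecule uniform arrival spread
    pife_factor: float = 1.0          # donor multiplier while enzyme in contact

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.salt not in SALTS:
            raise ValueError(f"unknown salt {self.salt!r}")
        if self.ligand.name not in LIGANDS:
            raise ValueError(f"unknown ligand {self.ligand.name!r}")
        for rate in (self.k_cat_unwind, self.k_exo_nt, self.k_fold,
                     self.k_intermediate, self.k_relax, self.ligand.k_on):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        for level in (self.E_duplex, self.E_ss, self.E_intermediate,
                      self.E_bound, *[m for m, _ in self.conformers]):
            if not 0.0 <= level <= 1.0:
                raise ValueError("FRET levels must lie in [0, 1]")
        if not 0.0 <= self.p_multistep <= 1.0:
            raise ValueError("p_multistep must lie in [0, 1]")
        if not 0.0 <= self.ligand.accessible_fraction <= 1.0:
            raise ValueError("accessible_fraction must lie in [0, 1]")
        w = sum(w for _, w in self.conformers)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("conformer weights must sum to 1")
        if self.construct.startswith("G") and self.construct[1:].isdigit():
            if self.overhang_len_nt != 6 * self.n_repeats:
                raise ValueError("telomeric overhang must be 6 nt per repeat")

    # -- derived quantities -------------------------------------------------

    @property
    def release_rate_per_nt(self) -> float:
        """Per-nucleotide strand-release rate for this preset's mode."""
        if self.mode == "vf_exo":
            return self.k_exo_nt
        return atp_release_rate(self.atp_uM, self.k_cat_unwind,
                                self.Km_atp, self.atp_hill)

    @property
    def conformer_means(self) -> tuple:
        return tuple(m for m, _ in self.conformers)

    def pathway_weights(self, multistep: bool) -> tuple:
        """Conformer weights for the one-step or multi-step pathway."""
        special = self.conformers_multistep if multistep else self.conformers_onestep
        pairs = special if special is not None else self.conformers
        return tuple(w for _, w in pairs)

    def overhang_sequence(self) -> str:
        """Overhang sequence (FASTA provenance export)."""
        if self.construct.startswith("G") and self.construct[1:].isdigit():
            return "TTAGGG" * self.n_repeats
        if self.construct == "cMyc":
            return "TGAGGGTGGGTAGGGTGGGTAA"
        if self.construct == "polyT":
            return "T" * self.overhang_len_nt
        if self.construct.startswith("mutant"):
            return ("TTAGGG" * self.n_repeats).replace("GGG", "GTG", 1)
        return "N" * self.overhang_len_nt

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticPreset":
        d = dict(d)
        lig = d.get("ligand")
        if isinstance(lig, dict):
            d["ligand"] = Ligand(**lig)
        for key in ("conformers", "conformers_onestep",
                    "conformers_multistep"):
            if d.get(key) is not None:
                d[key] = tuple(tuple(x) for x in d[key])
        if d.get("relax_weights") is not None:
            d["relax_weights"] = tuple(d["relax_weights"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Built-in registry
# ---------------------------------------------------------------------------

# Per-construct FRET geometry. Conformer levels for G2/G3/G4 follow the
# reported histogram peaks; the single-strand (ramp-end) level and the
# intermediate level are simulator choices, spaced so that duplex, ss,
# intermediate and final levels along any one molecule's path are separable
# at the +-0.07 band tolerance used by the classifier.
_CONSTRUCTS = {
    # name: (n_rep, conformers(pf weights), E_ss, E_int, p_multistep,
    #        vf one-step weights, vf multi-step weights, vf relax target)
    "G2": (2, ((0.75, 0.60), (0.90, 0.40)), 0.60, 0.675, 0.0,
           ((0.75, 1.0), (0.90, 0.0)), None),
    "G3": (3, ((0.65, 0.60), (0.80, 0.40)), 0.40, 0.60, 0.27,
           ((0.65, 1.0), (0.80, 0.0)), ((0.65, 0.0), (0.80, 1.0))),
    "G4": (4, ((0.70, 0.50), (0.85, 0.50)), 0.58, 0.715, 0.33,
           ((0.70, 0.75), (0.85, 0.25)), ((0.70, 0.0), (0.85, 1.0))),
    "G6": (6, ((0.60, 0.40), (0.75, 0.35), (0.88, 0.25)), 0.45, 0.665, 0.33,
           ((0.60, 0.40), (0.75, 0.45), (0.88, 0.15)),
           ((0.60, 0.0), (0.75, 0.0), (0.88, 1.0))),
    "G8": (8, ((0.55, 0.40), (0.68, 0.35), (0.82, 0.25)), 0.42, 0.62, 0.33,
           ((0.55, 0.40), (0.68, 0.45), (0.82, 0.15)),
           ((0.55, 0.0), (0.68, 0.0), (0.82, 1.0))),
    "cMyc": (0, ((0.90, 1.0),), 0.65, 0.775, 0.0, None, None),
    "mutant-G4": (4, ((0.65, 1.0),), 0.45, 0.55, 0.0, None, None),
}

_LIGANDS = {
    "C2": dict(conc_nM=250.0, k_on=2.0e-4),    # 0.05 s^-1 at 250 nM
    "POT1": dict(conc_nM=500.0, k_on=1.0e-4),  # 0.05 s^-1 at 500 nM
}

#: plateau (accessible) fractions per (mode-family, construct, ligand)
_ACCESS = {
    ("vf", "G2", "C2"): 1.0, ("vf", "G2", "POT1"): 1.0,
    ("vf", "G3", "C2"): 1.0, ("vf", "G3", "POT1"): 1.0,
    ("vf", "G4", "C2"): 0.70, ("vf", "G4", "POT1"): 0.85,
    ("pf", "G2", "C2"): 0.80, ("pf", "G2", "POT1"): 1.0,
    ("pf", "G3", "C2"): 0.80, ("pf", "G3", "POT1"): 1.0,
    ("pf", "G4", "C2"): 0.05, ("pf", "G4", "POT1"): 0.05,
    ("exo", "G4", "C2"): 0.93, ("exo", "G4", "POT1"): 0.92,
    ("salt", "G4", "C2"): 0.35, ("salt", "G4", "POT1"): 0.42,
}

K_RELAX_VF = 1.0 / (3 * 3600.0)  # ~3 h vf -> pf conformer relaxation


def _construct_kwargs(cname: str) -> dict:
    nrep, conf, e_ss, e_int, p_multi, w1, wm = _CONSTRUCTS[cname]
    return dict(construct=cname, n_repeats=nrep,
                overhang_len_nt=6 * nrep if nrep else 22,
                conformers=conf, E_ss=e_ss, E_intermediate=e_int,
                p_multistep=p_multi, conformers_onestep=w1,
                conformers_multistep=wm)


def _ligand(name: str, fam: str, cname: str) -> Ligand:
    if name == "none":
        return Ligand()
    acc = _ACCESS.get((fam, cname, name), 0.8)
    return Ligand(name=name, accessible_fraction=acc, **_LIGANDS[name])


def builtin_presets() -> dict:
    """Build the named preset registry covering the study's condition matrix."""
    reg: dict[str, KineticPreset] = {}

    def add(p: KineticPreset):
        reg[p.name] = p

    for cname in _CONSTRUCTS:
        base = _construct_kwargs(cname)
        # post-folding, three salts (no release pathway, so no step split)
        pf_base = dict(base, p_multistep=0.0, conformers_onestep=None,
                       conformers_multistep=None)
        for salt in SALTS:
            suffix = "" if salt == "KCl" else f"-{salt}"
            add(KineticPreset(name=f"pf-{cname}{suffix}", mode="pf",
                              salt=salt, **pf_base))
        # vectorial (Rep-X), three salts at 1 mM ATP
        vf = dict(base, k_relax=K_RELAX_VF,
                  relax_weights=tuple(w for _, w in base["conformers"]))
        for salt in SALTS:
            suffix = "" if salt == "KCl" else f"-{salt}"
            add(KineticPreset(name=f"vf-{cname}{suffix}", mode="vf_repx",
                              salt=salt, **vf))
        # ligand-capture presets (KCl)
        for lig in ("C2", "POT1"):
            add(KineticPreset(name=f"pf-{cname}-{lig}", mode="pf",
                              ligand=_ligand(lig, "pf", cname), **pf_base))
            add(KineticPreset(name=f"vf-{cname}-{lig}", mode="vf_repx",
                              ligand=_ligand(lig, "vf", cname), **vf))

    # ATP titration of vf-G4 (and matching ligand presets at 50 uM)
    g4vf = dict(_construct_kwargs("G4"), k_relax=K_RELAX_VF,
                relax_weights=(0.5, 0.5))
    for atp in (50, 100, 250, 500, 1000):
        add(KineticPreset(name=f"vf-G4-atp{atp}", mode="vf_repx",
                          atp_uM=float(atp), **g4vf))
    for lig in ("C2", "POT1"):
        add(KineticPreset(name=f"vf-G4-atp50-{lig}", mode="vf_repx",
                          atp_uM=50.0, ligand=_ligand(lig, "vf", "G4"), **g4vf))

    # lambda-exonuclease vectorial folding (PIFE on, ~>95% one-step)
    for cname in ("G2", "G4", "G6"):
        exo = dict(_construct_kwargs(cname), p_multistep=0.02,
                   k_relax=K_RELAX_VF,
                   relax_weights=tuple(w for _, w in _CONSTRUCTS[cname][1]))
        exo["E_ss"] = 0.58 if cname == "G4" else exo["E_ss"]
        add(KineticPreset(name=f"vf-exo-{cname}", mode="vf_exo",
                          pife_factor=1.5, **exo))
    for lig in ("C2", "POT1"):
        exo = dict(_construct_kwargs("G4"), p_multistep=0.02,
                   k_relax=K_RELAX_VF, relax_weights=(0.5, 0.5))
        add(KineticPreset(name=f"vf-exo-G4-{lig}", mode="vf_exo",
                          pife_factor=1.5, ligand=_ligand(lig, "exo", "G4"),
                          **exo))

    # LiCl -> KCl buffer-exchange folding of G4 (mid-FRET LiCl state at 0.65)
    salt_base = dict(_construct_kwargs("G4"), p_multistep=0.0)
    salt_base["E_ss"] = 0.65
    salt_base["conformers_onestep"] = ((0.70, 0.30), (0.85, 0.70))
    salt_base["conformers_multistep"] = None
    for lig in ("none", "C2", "POT1"):
        suffix = "" if lig == "none" else f"-{lig}"
        add(KineticPreset(name=f"salt-G4{suffix}", mode="salt_exchange",
                          salt="LiCl", ligand=_ligand(lig, "salt", "G4"),
                          **salt_base))

    # unstructured poly-thymine control: one constant level, no kinetics
    add(KineticPreset(name="pf-polyT", construct="polyT", n_repeats=0,
                      overhang_len_nt=25, mode="pf",
                      conformers=((0.35, 1.0),), E_ss=0.35,
                      E_intermediate=0.35))
    return reg


_REGISTRY: Optional[dict] = None


def get_preset(name: str) -> KineticPreset:
    """Look up a named preset; unknown names raise with a nearest-name hint."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = builtin_presets()
    try:
        return _REGISTRY[name]
    except KeyError:
        hint = difflib.get_close_matches(name, _REGISTRY, n=1)
        msg = f"unknown preset {name!r}"
        if hint:
            msg += f" (did you mean {hint[0]!r}?)"
        raise KeyError(msg) from None


def preset_names() -> list:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = builtin_presets()
    return sorted(_REGISTRY)


def dump_registry(path) -> None:
    """Write the full registry to a human-readable YAML file."""
    reg = {name: get_preset(name).to_dict() for name in preset_names()}
    with open(path, "w") as fh:
        yaml.safe_dump(reg, fh, sort_keys=True, default_flow_style=None)


def load_registry(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: KineticPreset.from_dict(d) for name, d in raw.items()}
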