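"""State process, observation process and parameter structures.

The latent annual state chain has three states: breeder (B), nonbreeder
(NB) and dead (D, absorbing).  Its one-year transition matrix is the
product of a diagonal survival matrix and a conditional breeding matrix::

    B  -> ( phi_B * psi_BB,   phi_B * (1 - psi_BB),   1 - phi_B  )
    NB -> ( phi_NB * psi_NBB, phi_NB * (1 - psi_NBB), 1 - phi_NB )
    D  -> ( 0,                0,                      1          )

where ``phi`` is apparent annual survival and ``psi`` the conditional
breeding probability given survival.

The observation process maps states to the 8 composite events through the
product of three row-stochastic matrices applied in the order
moult/winter -> uneven weeks -> even weeks:

* ``B_M`` (3 x 4): capture during moult/winter with probability ``m_B``
  (breeders) or ``m_NB`` (nonbreeders); the dead are never seen.
* ``B_U`` (4 x 6): capture of breeders during the uneven breeding weeks
  with probability ``p_u``; nonbreeders are not ashore in the breeding
  season and pass through unchanged.
* ``B_E`` (6 x 8): capture of breeders during the even weeks with
  probability ``b_e``; columns are the event codes 0-7.

The composite 3 x 8 product gives, per state, the probability of each
annual event; for a live breeder it factorizes into three independent
Bernoulli detections, one per capture period.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit as _expit, logit as _logit

from .errors import ValidationError

#: Latent states, in matrix row/column order.
STATES = ("B", "NB", "D")

#: Parameter families in working-vector order.
FAMILY_ORDER = ("phi", "psi", "m", "pu", "be")

#: Family -> state labels of its slots ("." = not state-indexed).
FAMILY_STATES = {
    "phi": ("B", "NB"),
    "psi": ("B", "NB"),   # departure state of the conditional breeding prob
    "m": ("B", "NB"),
    "pu": (".",),
    "be": (".",),
}


def expit(x):
    """Inverse logit link, mapping the working scale to (0, 1)."""
    return _expit(x)


def logit(p):
    """Logit link, mapping probabilities to the working scale."""
    return _logit(p)


def _check_prob(name, value):
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0) or np.any(~np.isfinite(arr)):
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")
    return arr


def build_transition_matrix(phi_b, phi_nb, psi_bb, psi_nbb) -> np.ndarray:
    """One-year 3 x 3 state-transition matrix (rows: B, NB, D departures)."""
    for name, v in (("phi_b", phi_b), ("phi_nb", phi_nb),
                    ("psi_bb", psi_bb), ("psi_nbb", psi_nbb)):
        _check_prob(name, v)
    survival = np.array([
        [phi_b, 0.0, 1.0 - phi_b],
        [0.0, phi_nb, 1.0 - phi_nb],
        [0.0, 0.0, 1.0],
    ])
    breeding = np.array([
        [psi_bb, 1.0 - psi_bb, 0.0],
        [psi_nbb, 1.0 - psi_nbb, 0.0],
        [0.0, 0.0, 1.0],
    ])
    return survival @ breeding


@dataclass(frozen=True)
class EventMatrixSet:
    """The three observation matrices and their composite product."""

    b_m: np.ndarray        # 3 x 4: states -> moult/winter outcome
    b_u: np.ndarray        # 4 x 6: -> uneven-week outcome
    b_e: np.ndarray        # 6 x 8: -> composite event codes 0-7
    composite: np.ndarray  # 3 x 8


def build_event_matrices(m_b, m_nb, p_u, b_e) -> EventMatrixSet:
    """Build the moult/uneven/even observation matrices and their product.

    Intermediate column order of ``b_m``: M_B, not-M_B, M_NB, not-M_NB;
    of ``b_u``: UM, not-U M, U, not-U, M_NB, not-M_NB.  Composite columns
    are the event codes 0..7 (NS, MUE, MU, ME, M, UE, U, E).
    """
    for name, v in (("m_b", m_b), ("m_nb", m_nb), ("p_u", p_u), ("b_e", b_e)):
        _check_prob(name, v)
    bm = np.array([
        [m_b, 1.0 - m_b, 0.0, 0.0],
        [0.0, 0.0, m_nb, 1.0 - m_nb],
        [0.0, 0.0, 0.0, 1.0],
    ])
    bu = np.array([
        [p_u, 1.0 - p_u, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, p_u, 1.0 - p_u, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 1.0],
    ])
    be = np.array([
        #  NS   MUE    MU     ME    M     UE     U     E
        [0.0, b_e, 1.0 - b_e, 0.0, 0.0, 0.0, 0.0, 0.0],          # seen U and M
        [0.0, 0.0, 0.0, b_e, 1.0 - b_e, 0.0, 0.0, 0.0],          # seen M only
        [0.0, 0.0, 0.0, 0.0, 0.0, b_e, 1.0 - b_e, 0.0],          # seen U only
        [1.0 - b_e, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, b_e],          # breeder unseen
        [0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0],                # NB seen in M
        [1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],                # NB/dead unseen
    ])
    return EventMatrixSet(bm, bu, be, bm @ bu @ be)


def composite_event_matrix(m_b, m_nb, p_u, b_e) -> np.ndarray:
    """3 x 8 state -> event probability matrix (product of the three stages)."""
    return build_event_matrices(m_b, m_nb, p_u, b_e).composite


class ParameterSet:
    """Real-scale probabilities expanded over the occasion axis.

    Survival and breeding probabilities are indexed by interval
    (``t -> t+1``, length ``T - 1``); detection probabilities by occasion
    (length ``T``).  Occasion 0 detection is never used by the conditioned
    likelihood but is stored for a uniform axis.
    """

    _INTERVAL = ("phi_b", "phi_nb", "psi_bb", "psi_nbb")
    _OCCASION = ("m_b", "m_nb", "p_u", "b_e")

    def __init__(self, T: int, *, phi_b, phi_nb, psi_bb, psi_nbb,
                 m_b, m_nb, p_u, b_e):
        if T < 1:
            raise ValidationError("need at least one occasion")
        self.T = int(T)
        for name in self._INTERVAL:
            setattr(self, name, self._expand(name, locals()[name], max(self.T - 1, 1)))
        for name in self._OCCASION:
            setattr(self, name, self._expand(name, locals()[name], self.T))

    @staticmethod
    def _expand(name, value, length):
        arr = np.broadcast_to(_check_prob(name, value), (length,)).astype(float).copy()
        return arr

    @classmethod
    def constant(cls, T: int, *, phi=None, psi=None, m=None,
                 phi_b=None, phi_nb=None, psi_bb=None, psi_nbb=None,
                 m_b=None, m_nb=None, p_u=0.5, b_e=0.5) -> "ParameterSet":
        """Build a time-constant set; ``phi``/``psi``/``m`` broadcast over states."""
        return cls(
            T,
            phi_b=phi_b if phi_b is not None else phi,
            phi_nb=phi_nb if phi_nb is not None else phi,
            psi_bb=psi_bb if psi_bb is not None else psi,
            psi_nbb=psi_nbb if psi_nbb is not None else psi,
            m_b=m_b if m_b is not None else m,
            m_nb=m_nb if m_nb is not None else m,
            p_u=p_u, b_e=b_e,
        )

    def transition_matrices(self) -> np.ndarray:
        """(T-1, 3, 3) stack of per-interval transition matrices."""
        return np.stack([
            build_transition_matrix(self.phi_b[t], self.phi_nb[t],
                                    self.psi_bb[t], self.psi_nbb[t])
            for t in range(self.T - 1)
        ]) if self.T > 1 else np.zeros((0, 3, 3))

    def event_matrices(self) -> np.ndarray:
        """(T, 3, 8) stack of per-occasion composite event matrices."""
        return np.stack([
            composite_event_matrix(self.m_b[t], self.m_nb[t],
                                   self.p_u[t], self.b_e[t])
            for t in range(self.T)
        ])

    def as_dict(self) -> dict:
        return {name: getattr(self, name).tolist()
                for name in self._INTERVAL + self._OCCASION}


@dataclass(frozen=True)
class Pattern:
    """Variation pattern of one parameter family."""

    by_state: bool = False
    by_time: bool = False

    @property
    def label(self) -> str:
        if self.by_state and self.by_time:
            return "state*t"
        if self.by_state:
            return "state"
        if self.by_time:
            return "t"
        return "."


_PATTERN_TOKENS = {
    ".": Pattern(False, False),
    "t": Pattern(False, True),
    "s": Pattern(True, False),
    "state": Pattern(True, False),
    "s*t": Pattern(True, True),
    "state*t": Pattern(True, True),
    "t*s": Pattern(True, True),
    "t*state": Pattern(True, True),
}


@dataclass(frozen=True)
class ModelStructure:
    """Maps a working-scale vector to a :class:`ParameterSet`.

    Each family (phi, psi, m, pu, be) carries a variation pattern; a family
    may instead be fixed at a real-scale constant (no working slots), e.g.
    perfect detection ``fixed={"m": 1, "pu": 1, "be": 1}``.

    Working-vector layout (stable across versions): family-major in the
    order phi, psi, m, pu, be; within a family, state-major (B block, then
    NB); within a state, time-ordered.  Time slots per family: the T - 1
    intervals for phi and psi, and occasions 1..T-1 for detection families
    (occasion-0 detection is conditioned away and takes the occasion-1
    value).  The link is logit for every slot.
    """

    phi: Pattern = Pattern()
    psi: Pattern = Pattern()
    m: Pattern = Pattern()
    pu: Pattern = Pattern()
    be: Pattern = Pattern()
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for fam, value in self.fixed.items():
            if fam not in FAMILY_ORDER:
                raise ValidationError(f"unknown parameter family {fam!r}")
            _check_prob(fam, value)
        for fam in ("pu", "be"):
            if getattr(self, fam).by_state:
                raise ValidationError(
                    f"{fam} is a breeder-only capture probability and cannot "
                    "vary by state")

    # -- slot bookkeeping ---------------------------------------------------

    def _free_families(self):
        return [f for f in FAMILY_ORDER if f not in self.fixed]

    def _slots(self, family: str, T: int) -> tuple[int, int]:
        """(n_state_levels, n_time_levels) of a free family."""
        pat: Pattern = getattr(self, family)
        n_state = len(FAMILY_STATES[family]) if pat.by_state else 1
        n_time = (T - 1) if pat.by_time else 1
        return n_state, n_time

    def parameter_count(self, T: int) -> int:
        """Number of working-scale slots (raw count, before identifiability)."""
        if T < 2:
            raise ValidationError("need at least two occasions for a model")
        if not self._free_families():
            raise ValidationError("structure has no free parameters")
        return sum(ns * nt for ns, nt in
                   (self._slots(f, T) for f in self._free_families()))

    def slot_labels(self, T: int) -> list[tuple[str, str, int]]:
        """(family, state, time index) per working slot, in layout order."""
        labels = []
        for fam in self._free_families():
            pat: Pattern = getattr(self, fam)
            states = FAMILY_STATES[fam] if pat.by_state else (".",)
            n_time = (T - 1) if pat.by_time else 1
            for s in states:
                for t in range(n_time):
                    labels.append((fam, s, t if pat.by_time else -1))
        return labels

    # -- expansion ----------------------------------------------------------

    def expand(self, beta: Sequence[float], T: int) -> ParameterSet:
        """Apply the inverse link and broadcast patterns into a ParameterSet."""
        beta = np.asarray(beta, dtype=float)
        expected = self.parameter_count(T)
        if beta.shape != (expected,):
            raise ValidationError(
                f"working vector has length {beta.size}, structure expects {expected}")
        values: dict[str, np.ndarray] = {}
        pos = 0
        for fam in FAMILY_ORDER:
            n_levels = len(FAMILY_STATES[fam])
            if fam in self.fixed:
                block = np.full((n_levels, T - 1), float(self.fixed[fam]))
            else:
                ns, nt = self._slots(fam, T)
                raw = expit(beta[pos:pos + ns * nt]).reshape(ns, nt)
                pos += ns * nt
                block = np.broadcast_to(raw, (n_levels, nt)) if ns == 1 else raw
                block = np.broadcast_to(block[:, :1], (n_levels, T - 1)) if nt == 1 \
                    else block
            values[fam] = np.asarray(block, dtype=float)

        def occ(fam_block):
            # detection families: slots cover occasions 1..T-1; occasion 0 pads
            return np.concatenate([fam_block[:, :1], fam_block], axis=1)

        m = occ(values["m"])
        pu = occ(values["pu"])
        be = occ(values["be"])
        return ParameterSet(
            T,
            phi_b=values["phi"][0], phi_nb=values["phi"][1],
            psi_bb=values["psi"][0], psi_nbb=values["psi"][1],
            m_b=m[0], m_nb=m[1], p_u=pu[0], b_e=be[0],
        )

    # -- parsing ------------------------------------------------------------

    _TOKEN_RE = re.compile(r"([a-z_]+)\(([^()]*)\)")

    @classmethod
    def parse(cls, text: str) -> "ModelStructure":
        """Parse a structure string like ``"phi(.) psi(state*t) m(state*t) pu(t) be(t)"``.

        Pattern tokens: ``.`` constant, ``t`` time, ``state`` (or ``s``)
        state, ``state*t`` both; ``=<value>`` fixes the family at a
        real-scale constant.  Unlisted families default to constant.
        """
        text = text.strip()
        if not text:
            raise ValidationError(
                "empty structure string; expected tokens like "
                "'phi(.) psi(state*t) m(state*t) pu(t) be(t)'")
        consumed = cls._TOKEN_RE.sub("", text).strip()
        if consumed:
            raise ValidationError(
                f"could not parse structure fragment {consumed!r}; grammar is "
                "family(pattern) with family in {phi,psi,m,pu,be} and pattern "
                "in {., t, state, state*t, =<value>}")
        patterns: dict[str, Pattern] = {}
        fixed: dict[str, float] = {}
        for fam, token in cls._TOKEN_RE.findall(text):
            if fam not in FAMILY_ORDER:
                raise ValidationError(
                    f"unknown parameter family {fam!r}; expected one of {FAMILY_ORDER}")
            token = token.strip()
            if token.startswith("="):
                fixed[fam] = float(token[1:])
            elif token in _PATTERN_TOKENS:
                patterns[fam] = _PATTERN_TOKENS[token]
            else:
                raise ValidationError(
                    f"unknown pattern {token!r} for family {fam!r}; expected "
                    "one of ., t, state, state*t, =<value>")
        return cls(fixed=fixed, **patterns)

    def to_string(self) -> str:
        parts = []
        for fam in FAMILY_ORDER:
            if fam in self.fixed:
                parts.append(f"{fam}(={self.fixed[fam]:g})")
            else:
                parts.append(f"{fam}({getattr(self, fam).label})")
        return " ".join(parts)

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "ModelStructure":
        """Build from a YAML-style mapping, e.g.
        ``{"phi": {"by_state": false, "by_time": false}, "m": {"fixed": 1.0}}``.
        """
        patterns: dict[str, Pattern] = {}
        fixed: dict[str, float] = {}
        for fam, sub in cfg.items():
            if fam not in FAMILY_ORDER:
                raise ValidationError(f"unknown parameter family {fam!r}")
            if "fixed" in sub:
                fixed[fam] = float(sub["fixed"])
            else:
                patterns[fam] = Pattern(bool(sub.get("by_state", False)),
                                        bool(sub.get("by_time", False)))
        return cls(fixed=fixed, **patterns)
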