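"""Semi-quantitative graft-union scoring and within-stratum ranking.

Graft unions are coded on six ordinal/categorical axes:

* callogenesis 1-4 (1 broken/unattached union ... 4 perfect union),
* bionts involved in the connection — intensity 0-3 for each of
  a (scion rays), b (scion cambium), c (rootstock rays), d (rootstock
  cambium), written like ``"3a, 2b, 3c, 3d"``,
* internal callus type: 0 non-vascular, 1 differentiated without
  meristemoids, 2 differentiated with meristemoids, -1 necrotized
  (several codes may co-occur, e.g. ``"1; -1"``),
* external callus: 0 non-vascular, 1 differentiated,
* necrosis location: subset of {S, R} (``"np"`` = not present),
* space between bionts: yes/no.

Ranking within a stratum (one cultivar/caliber at one survey time) uses
a pluggable lexicographic policy.  The default priority is: higher
callogenesis, absence of necrotized callus, fewer necrotic bionts,
higher total involvement, higher callus differentiation.  Ties share the
better rank and ranks are dense (1, 1, 2, ...).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .errors import InvalidInputError, VocabularyError

__all__ = [
    "GraftObservation",
    "GraftScore",
    "DEFAULT_POLICY",
    "CRITERIA",
    "encode_observation",
    "rank_grafts",
    "load_printed_evaluations",
    "ranking_concordance",
]

_BIONT_CODES = ("a", "b", "c", "d")
_CALLUS_CODES = {0, 1, 2, -1}
_DASHES = {"–": "-", "−": "-", "—": "-"}


def _normalize(token: str) -> str:
    for bad, good in _DASHES.items():
        token = token.replace(bad, good)
    return token.strip()


@dataclass(frozen=True)
class GraftObservation:
    """One coded graft-union annotation."""

    callogenesis: int
    involvement: Mapping[str, int]  # {a,b,c,d} -> 0..3
    callus_type: frozenset          # subset of {0, 1, 2, -1}
    external_callus: int            # 0 or 1
    necrosis: frozenset             # subset of {"S", "R"}; empty = np
    space_between_bionts: bool
    stratum: tuple = ()
    label: str = ""

    def __post_init__(self) -> None:
        if self.callogenesis not in (1, 2, 3, 4):
            raise VocabularyError(f"callogenesis must be 1-4, got {self.callogenesis}")
        for code, level in self.involvement.items():
            if code not in _BIONT_CODES:
                raise VocabularyError(f"unknown biont code {code!r}")
            if level not in (0, 1, 2, 3):
                raise VocabularyError(f"involvement intensity must be 0-3, got {level}")
        if not set(self.callus_type) <= _CALLUS_CODES:
            bad = set(self.callus_type) - _CALLUS_CODES
            raise VocabularyError(f"unknown callus type code(s) {sorted(bad)}")
        if self.external_callus not in (0, 1):
            raise VocabularyError(f"external callus must be 0 or 1, got {self.external_callus}")
        if not set(self.necrosis) <= {"S", "R"}:
            bad = set(self.necrosis) - {"S", "R"}
            raise VocabularyError(f"unknown necrosis location(s) {sorted(bad)}")

    @property
    def total_involvement(self) -> int:
        return sum(self.involvement.values())

    @property
    def has_necrotized_callus(self) -> bool:
        return -1 in self.callus_type

    @property
    def callus_differentiation(self) -> int:
        nonneg = [c for c in self.callus_type if c >= 0]
        return max(nonneg) if nonneg else 0

    @property
    def necrosis_burden(self) -> int:
        return len(self.necrosis)


@dataclass(frozen=True)
class GraftScore:
    observation: GraftObservation
    score: tuple
    rank: int


def _parse_involvement(text: str) -> dict[str, int]:
    out = {c: 0 for c in _BIONT_CODES}
    for token in re.split(r"[,;]", _normalize(text)):
        token = token.strip()
        if not token:
            continue
        m = re.fullmatch(r"(\d+)\s*([a-d])", token)
        if not m:
            raise VocabularyError(f"cannot parse involvement token {token!r}")
        level, code = int(m.group(1)), m.group(2)
        if level > 3:
            raise VocabularyError(
                f"involvement intensity out of range in token {token!r} (max 3)"
            )
        out[code] = level
    return out


def _parse_callus(text: str) -> frozenset:
    codes = set()
    for token in re.split(r"[,;]", _normalize(str(text))):
        token = token.strip()
        if not token:
            continue
        try:
            code = int(token)
        except ValueError:
            raise VocabularyError(f"cannot parse callus type token {token!r}") from None
        if code not in _CALLUS_CODES:
            raise VocabularyError(f"callus type code {code} outside {{0, 1, 2, -1}}")
        codes.add(code)
    return frozenset(codes)


def _parse_necrosis(text: str) -> frozenset:
    text = _normalize(str(text))
    if text.lower() in ("np", "", "nan"):
        return frozenset()
    locs = set()
    for token in re.split(r"[,;]|\be\b|\band\b", text):
        token = token.strip()
        if not token:
            continue
        if token not in ("S", "R"):
            raise VocabularyError(f"unknown necrosis token {token!r}")
        locs.add(token)
    return frozenset(locs)


def _parse_space(text) -> bool:
    s = _normalize(str(text)).lower()
    if s in ("yes", "y", "true", "1"):
        return True
    if s in ("no", "n", "false", "0"):
        return False
    raise VocabularyError(f"space between bionts must be yes/no, got {text!r}")


def encode_observation(raw: Mapping) -> GraftObservation:
    """Parse one raw annotation row into a :class:`GraftObservation`.

    ``raw`` is a mapping with keys ``callogenesis``, ``involvement``,
    ``callus_type``, ``external_callus``, ``necrosis``, ``space`` and
    optionally ``stratum`` (tuple) and ``label``.
    """
    try:
        callo = int(raw["callogenesis"])
    except (KeyError, TypeError, ValueError):
        raise VocabularyError(f"bad callogenesis value {raw.get('callogenesis')!r}") from None
    return GraftObservation(
        callogenesis=callo,
        involvement=_parse_involvement(str(raw.get("involvement", ""))),
        callus_type=_parse_callus(raw.get("callus_type", "0")),
        external_callus=int(raw.get("external_callus", 0)),
        necrosis=_parse_necrosis(raw.get("necrosis", "np")),
        space_between_bionts=_parse_space(raw.get("space", "yes")),
        stratum=tuple(raw.get("stratum", ())),
        label=str(raw.get("label", "")),
    )


# criterion name -> key function; LARGER is better for every key
CRITERIA: dict[str, Callable[[GraftObservation], float]] = {
    "callogenesis": lambda o: o.callogenesis,
    "no_necrotized_callus": lambda o: 0 if o.has_necrotized_callus else 1,
    "low_necrosis_burden": lambda o: -o.necrosis_burden,
    "involvement": lambda o: o.total_involvement,
    "callus_differentiation": lambda o: o.callus_differentiation,
    "external_callus": lambda o: o.external_callus,
    "no_space": lambda o: 0 if o.space_between_bionts else 1,
}

DEFAULT_POLICY: tuple[str, ...] = (
    "callogenesis",
    "no_necrotized_callus",
    "low_necrosis_burden",
    "involvement",
    "callus_differentiation",
)


def rank_grafts(
    observations: Sequence[GraftObservation],
    policy: Sequence[str] = DEFAULT_POLICY,
) -> list[GraftScore]:
    """Rank observations of one stratum under a lexicographic policy.

    Returns scores in the input order.  Ranks are dense: tied
    observations share the better rank and the next distinct score gets
    the next integer.
    """
    observations = list(observations)
    if len(observations) < 2:
        raise InvalidInputError("ranking needs >= 2 observations in a stratum")
    strata = {o.stratum for o in observations}
    if len(strata) > 1:
        raise InvalidInputError(f"mixed strata in one ranking call: {sorted(strata)}")
    unknown = [c for c in policy if c not in CRITERIA]
    if unknown:
        raise InvalidInputError(f"unknown policy criteria: {unknown}")

    scores = [tuple(CRITERIA[c](o) for c in policy) for o in observations]
    distinct = sorted(set(scores), reverse=True)
    rank_of = {s: i + 1 for i, s in enumerate(distinct)}
    return [
        GraftScore(observation=o, score=s, rank=rank_of[s])
        for o, s in zip(observations, scores)
    ]


def load_printed_evaluations(trial: int = 1) -> pd.DataFrame:
    """Load the packaged coded graft evaluations (trial 1: three cultivars
    x three techniques; trial 2: Glera, six technique/caliber combinations),
    including the published ranking column."""
    name = {
        1: "trial1_graft_evaluation.csv",
        2: "trial2_caliber_graft_evaluation.csv",
    }.get(trial)
    if name is None:
        raise InvalidInputError("trial must be 1 or 2")
    with resources.files("xylograft.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def ranking_concordance(
    table: pd.DataFrame, policy: Sequence[str] = DEFAULT_POLICY
) -> dict:
    """Compare policy ranks with a published ranking column.

    ``table`` needs columns ``stratum_*`` (any columns starting with
    ``stratum_``), the six coding columns and ``printed_rank``.  Returns
    ``{"n": ..., "matches": ..., "concordance": ..., "deviations": [...]}``
    where each deviation names the stratum, member, computed and printed
    rank.
    """
    stratum_cols = [c for c in table.columns if c.startswith("stratum_")]
    if not stratum_cols or "printed_rank" not in table.columns:
        raise InvalidInputError("table needs stratum_* columns and printed_rank")
    matches = 0
    total = 0
    deviations = []
    for stratum, grp in table.groupby(stratum_cols, sort=False):
        obs = [
            encode_observation({**row, "stratum": stratum, "label": row.get("label", "")})
            for row in grp.to_dict("records")
        ]
        ranked = rank_grafts(obs, policy)
        for score, (_, row) in zip(ranked, grp.iterrows()):
            total += 1
            if score.rank == int(row["printed_rank"]):
                matches += 1
            else:
                deviations.append(
                    {
                        "stratum": stratum,
                        "label": score.observation.label,
                        "computed_rank": score.rank,
                        "printed_rank": int(row["printed_rank"]),
                    }
                )
    return {
        "n": total,
        "matches": matches,
        "concordance": matches / total if total else float("nan"),
        "deviations": deviations,
        "policy": tuple(policy),
    }
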