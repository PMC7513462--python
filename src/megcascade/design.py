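"""Morphed-character stimulus space and orthogonalized trial designs.

The experiment shows briefly flashed characters that are parametric morphs
between a letter and a digit endpoint (a single "pixel" bar whose contrast is
stepped through eight equally spaced values).  Five trial features are
manipulated orthogonally:

1. ``position``     -- stimulus left or right of fixation (+1 / -1)
2. ``identity``     -- which morph continuum the stimulus comes from (+1 / -1)
3. ``category``     -- letter vs digit (+1 / -1); on ambiguous trials the
   category is defined by the subject's *report*, on unambiguous trials by the
   stimulus itself
4. ``uncertainty``  -- 1 - |2c - 1| for pixel contrast c, i.e. 0 at the
   endpoints and maximal for near-50% contrast
5. ``motor``        -- which button was pressed (+1 / -1); the identity-button
   mapping alternates across blocks so that motor responses decorrelate from
   identity and category

The full factorial over {position x continuum x evidence step x mapping},
replicated and shuffled, makes the five features pairwise uncorrelated over the
active trials.  Passive trials (no response required) use distinct, unambiguous
endpoint characters and are appended at the end of each block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEATURES",
    "LETTERS",
    "DIGITS",
    "KNOWN_CHARS",
    "MorphStimulus",
    "make_morph_continuum",
    "generate_design",
    "feature_orthogonality",
]

#: Canonical order of the five orthogonal trial features.
FEATURES = ("position", "identity", "category", "uncertainty", "motor")

#: Column names in a trial table corresponding to :data:`FEATURES`.
FEATURE_COLUMNS = {
    "position": "position_code",
    "identity": "identity_code",
    "category": "category_code",
    "uncertainty": "uncertainty",
    "motor": "motor_code",
}

LETTERS = frozenset("ACEHOS")
DIGITS = frozenset("045689")
KNOWN_CHARS = LETTERS | DIGITS


@dataclass(frozen=True)
class MorphStimulus:
    """One stimulus on a letter/digit morph continuum."""

    morph_id: str
    step: int
    contrast: float
    endpoint_chars: tuple[str, str]
    position: str = "left"
    flankers: bool = True

    @property
    def uncertainty(self) -> float:
        """0 at the unambiguous endpoints, maximal near 50% pixel contrast."""
        return 1.0 - abs(2.0 * self.contrast - 1.0)


def _check_char(char: str) -> str:
    c = str(char).upper()
    if c not in KNOWN_CHARS:
        raise ValueError(
            f"unknown character {char!r}; known characters: "
            f"{''.join(sorted(KNOWN_CHARS))}"
        )
    return c


def make_morph_continuum(
    endpoint_chars: Sequence[str],
    n_steps: int = 8,
    position: str = "left",
    flankers: bool = True,
) -> list[MorphStimulus]:
    """Build a morph continuum between two endpoint characters.

    The morphable pixel's contrast takes ``n_steps`` equally spaced values on
    [0, 1]; steps ``1`` and ``n_steps`` are the unambiguous endpoints.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    a, b = (_check_char(c) for c in endpoint_chars)
    contrasts = np.linspace(0.0, 1.0, n_steps)
    morph_id = f"{a}-{b}"
    return [
        MorphStimulus(
            morph_id=morph_id,
            step=i + 1,
            contrast=float(c),
            endpoint_chars=(a, b),
            position=position,
            flankers=flankers,
        )
        for i, c in enumerate(contrasts)
    ]


def _is_letter(char: str) -> bool:
    return char in LETTERS


def _continuum_rows(
    continuum: Sequence[str], n_steps: int
) -> pd.DataFrame:
    """Per-step stimulus attributes for one continuum (letter at contrast 0)."""
    stimuli = make_morph_continuum(continuum, n_steps)
    first_is_letter = _is_letter(stimuli[0].endpoint_chars[0])
    rows = []
    for s in stimuli:
        letter_evidence = (1.0 - s.contrast) if first_is_letter else s.contrast
        rows.append(
            {
                "continuum": s.morph_id,
                "evidence_step": s.step,
                "contrast": s.contrast,
                "letter_evidence": letter_evidence,
                "uncertainty": s.uncertainty,
            }
        )
    return pd.DataFrame(rows)


def generate_design(
    n_blocks: int = 40,
    trials_per_block: int = 48,
    passive_per_block: int = 8,
    seed: int = 0,
    active_continua: tuple[Sequence[str], Sequence[str]] = (("E", "6"), ("H", "4")),
    passive_continua: tuple[Sequence[str], Sequence[str]] = (("A", "9"), ("C", "8")),
    n_steps: int = 8,
) -> pd.DataFrame:
    """Generate the orthogonalized two-alternative forced-choice design.

    Active trials form a full factorial over {position(2) x continuum(2) x
    evidence step(``n_steps``) x mapping(2)}, replicated across the experiment
    and shuffled with ``seed``.  The identity-button ``mapping`` alternates
    across blocks, so each block contains a single mapping level.  Passive
    trials (unambiguous endpoints of held-out continua) are appended at the end
    of every block; they carry no motor code and no reaction time.

    Defaults reproduce the 1920-trial / 40-block / 320-passive design.

    Behavioral columns (``report``, ``rt_ms``, ``correct``) are NaN until
    filled by :func:`megcascade.synthetic.simulate_behavior`; ``category_code``
    and ``motor_code`` are provisionally derived from the stimulus and are
    overwritten by the report on ambiguous trials.
    """
    active_per_block = trials_per_block - passive_per_block
    if active_per_block <= 0:
        raise ValueError("trials_per_block must exceed passive_per_block")
    n_active = n_blocks * active_per_block
    cell_count = 2 * 2 * n_steps * 2  # position x continuum x step x mapping
    if n_active % cell_count:
        raise ValueError(
            f"active trial count {n_active} is not divisible by the factorial "
            f"size {cell_count}"
        )
    if n_blocks % 2:
        raise ValueError("n_blocks must be even so the mapping alternates evenly")
    per_mapping = n_active // 2
    blocks_per_mapping = n_blocks // 2
    if per_mapping % blocks_per_mapping:
        raise ValueError(
            "active trials per mapping level do not divide evenly into blocks"
        )

    rng = np.random.default_rng(seed)
    cont_info = {
        i: _continuum_rows(c, n_steps) for i, c in enumerate(active_continua)
    }

    # factorial pool per mapping level: position x continuum x step, replicated
    reps = per_mapping // (2 * 2 * n_steps)
    base = []
    for pos in (+1, -1):
        for ic, (cid, info) in enumerate(cont_info.items()):
            ident = +1 if ic == 0 else -1
            for _, row in info.iterrows():
                base.append((pos, ident, row))
    pools = {}
    for mapping in (+1, -1):
        pool = base * reps
        order = rng.permutation(len(pool))
        pools[mapping] = [pool[i] for i in order]

    passive_info = [
        _continuum_rows(c, n_steps) for c in passive_continua
    ]
    passive_cells = []
    for pos in (+1, -1):
        for ic, info in enumerate(passive_info):
            ident = +1 if ic == 0 else -1
            for step in (1, n_steps):
                row = info[info.evidence_step == step].iloc[0]
                passive_cells.append((pos, ident, row))

    records = []
    taken = {+1: 0, -1: 0}
    for block in range(n_blocks):
        mapping = +1 if block % 2 == 0 else -1
        start = taken[mapping]
        chunk = pools[mapping][start : start + active_per_block]
        taken[mapping] += active_per_block
        for pos, ident, row in chunk:
            stim_category = 1.0 if row.letter_evidence > 0.5 else -1.0
            records.append(
                {
                    "block": block,
                    "active": True,
                    "position_code": float(pos),
                    "continuum": row.continuum,
                    "identity_code": float(ident),
                    "evidence_step": int(row.evidence_step),
                    "contrast": row.contrast,
                    "letter_evidence": row.letter_evidence,
                    "uncertainty": row.uncertainty,
                    "category_code": stim_category,
                    "mapping": float(mapping),
                    "motor_code": float(mapping) * ident * stim_category,
                    "report": np.nan,
                    "rt_ms": np.nan,
                    "correct": np.nan,
                }
            )
        if passive_per_block:
            idx = rng.permutation(len(passive_cells))
            sel = [passive_cells[i] for i in idx[:passive_per_block]]
            for pos, ident, row in sel:
                stim_category = 1.0 if row.letter_evidence > 0.5 else -1.0
                records.append(
                    {
                        "block": block,
                        "active": False,
                        "position_code": float(pos),
                        "continuum": row.continuum,
                        "identity_code": float(ident),
                        "evidence_step": int(row.evidence_step),
                        "contrast": row.contrast,
                        "letter_evidence": row.letter_evidence,
                        "uncertainty": row.uncertainty,
                        "category_code": stim_category,
                        "mapping": float(mapping),
                        "motor_code": np.nan,
                        "report": np.nan,
                        "rt_ms": np.nan,
                        "correct": np.nan,
                    }
                )
    table = pd.DataFrame.from_records(records)
    table.index.name = "trial"
    return table


def feature_orthogonality(
    table: pd.DataFrame, validate: bool = False, tol: float = 0.05
) -> pd.DataFrame:
    """Pairwise Pearson correlations between the five trial features.

    Computed over active trials only.  A constant feature column makes the
    correlation undefined and raises.  With ``validate=True`` the call fails if
    any off-diagonal correlation exceeds ``tol`` in magnitude.
    """
    active = table[table["active"].astype(bool)]
    if len(active) < 2:
        raise ValueError("need at least 2 active trials")
    cols = [FEATURE_COLUMNS[f] for f in FEATURES]
    X = active[cols].to_numpy(float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"constant feature column(s): {bad}; correlation undefined")
    corr = np.corrcoef(X, rowvar=False)
    out = pd.DataFrame(corr, index=list(FEATURES), columns=list(FEATURES))
    if validate:
        off = np.abs(corr - np.eye(len(FEATURES)))
        if off.max() > tol:
            i, j = np.unravel_index(np.argmax(off), off.shape)
            raise ValueError(
                f"features {FEATURES[i]!r} and {FEATURES[j]!r} correlate at "
                f"r={corr[i, j]:.3f} (tolerance {tol})"
            )
    return out
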