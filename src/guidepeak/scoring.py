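"""Predicted cleavage scores from mismatch-penalty models.

Two model families are supported, both multiplicative over mismatches
and normalised so a perfect protospacer with a canonical PAM scores 1:

* a position-weight model (Hsu-Zhang 2013 style): per-position penalty
  weights ``w_p``; score = prod(1 - w_p) over mismatched positions,
  times a mean-pairwise-distance term, times 1/n^2 for n >= 2
  mismatches — clustered mismatches hurt less than spread-out ones;
* a substitution-score table (CFD style): per-(position, guide base,
  genome base) activity factors times a PAM activity factor.

Positions are 1-based from the PAM-distal end of the guide. Guides
longer than a model are handled by padding neutral values (weight 0 /
factor 1) at the PAM-distal start, the standard way of borrowing the
SpCas9 model for, e.g., a 24-nt NmCas9 guide.

The packaged Hsu-Zhang weight vector is the published one; the packaged
CFD-style table is a synthetic stand-in (see its header) — supply the
published table through the user-matrix TSV interface for real CFD
predictions. Packaged files are checksum-validated at load.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .dna import iupac_match

_PACKAGED_SHA256 = {
    "hsu_zhang_2013_weights.tsv":
        "db03b712174c5707fcfd36c97294c09665a3818a425665f06d81214c486c9a5d",
    "cfd_table.synthetic.tsv":
        "4771f2f679f80d5c359f5194589e3f78cb98fb0324b4b5c78af6e48001958ebf",
    "cfd_pam.synthetic.tsv":
        "16ec20bcc9bd3210a9dd2df9887f8c04d206760996ddc32fa1a79c95be0ccd7b",
}

BUILTIN_MODELS = ("hsu_zhang_2013", "cfd_2016")


@dataclass(frozen=True)
class PositionWeightModel:
    weights: tuple[float, ...]   # index 0 = position 1 = PAM-distal end
    name: str = "user"

    def __post_init__(self) -> None:
        for w in self.weights:
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"weight {w} outside [0, 1]")

    @property
    def guide_length(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class SubstitutionScoreTable:
    entries: dict            # (position, guide_base, genome_base) -> factor
    pam_factors: tuple       # ((iupac mask, factor), ...), tried in order
    guide_length: int
    name: str = "user"
    default_factor: float | None = None

    def __post_init__(self) -> None:
        for k, f in self.entries.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"factor {f} for {k} outside [0, 1]")
        for _, f in self.pam_factors:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"PAM factor {f} outside [0, 1]")

    def pam_factor(self, pam_seq: str) -> float:
        for mask, f in self.pam_factors:
            if len(mask) == len(pam_seq) and iupac_match(mask, pam_seq):
                return f
        raise KeyError(f"no PAM factor matches {pam_seq!r}")


def hsu_zhang_score(mismatch_positions: Sequence[int], model: PositionWeightModel,
                    ) -> float:
    """Position-weight cleavage score in [0, 1].

    score = prod_{p in mm} (1 - w_p)
            * 1 / (((L-1 - dbar) / (L-1)) * 4 + 1)
            * 1 / n^2

    with n mismatches, dbar the mean pairwise distance between mismatch
    positions and L the guide length (denominator 19 for the canonical
    20-nt guide). n = 0 gives 1; for n = 1 the distance term and 1/n^2
    are both defined as 1.
    """
    L = model.guide_length
    mm = sorted(mismatch_positions)
    for p in mm:
        if not 1 <= p <= L:
            raise ValueError(f"mismatch position {p} outside 1..{L}")
    n = len(mm)
    if n == 0:
        return 1.0
    score = 1.0
    for p in mm:
        score *= 1.0 - model.weights[p - 1]
    if n == 1:
        return score
    dsum = sum(mm[j] - mm[i] for i in range(n) for j in range(i + 1, n))
    dbar = dsum / (n * (n - 1) / 2)
    score *= 1.0 / (((L - 1 - dbar) / (L - 1)) * 4 + 1)
    score *= 1.0 / (n * n)
    return score


def cfd_score(mismatch_detail: Iterable[tuple[int, str, str]], pam_seq: str,
              table: SubstitutionScoreTable) -> float:
    """Substitution-table cleavage score in [0, 1].

    Product over mismatches of the (position, guide base, genome base)
    factor, times the PAM factor for the observed PAM. A missing entry
    uses the table's default factor, or raises naming the tuple.
    """
    score = 1.0
    for pos, g, b in mismatch_detail:
        key = (pos, g.upper(), b.upper())
        if key in table.entries:
            score *= table.entries[key]
        elif table.default_factor is not None:
            score *= table.default_factor
        else:
            raise KeyError(f"no substitution factor for {key}")
    return score * table.pam_factor(pam_seq.upper())


def score_site(site, model) -> float:
    """Dispatch on model type; ``site`` is an OffTargetSite."""
    if isinstance(model, PositionWeightModel):
        return hsu_zhang_score([p for p, _, _ in site.mismatch_detail], model)
    return cfd_score(site.mismatch_detail, site.pam_seq, model)


def _read_packaged(name: str) -> str:
    data = resources.files("guidepeak.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _PACKAGED_SHA256[name]:
        raise RuntimeError(f"packaged data file {name} failed checksum validation")
    return data.decode()


def _parse_rows(text: str) -> list[list[str]]:
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows[1:] if rows and not _is_numeric(rows[0][-1]) else rows


def _is_numeric(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _pad_weights(weights: list[float], guide_length: int, name: str,
                 ) -> PositionWeightModel:
    if guide_length < len(weights):
        raise ValueError(f"guide_length {guide_length} shorter than model "
                         f"{name} ({len(weights)} positions)")
    pad = guide_length - len(weights)
    return PositionWeightModel(weights=tuple([0.0] * pad + weights), name=name)


def load_position_weights(rows: list[list[str]], guide_length: int, name: str,
                          ) -> PositionWeightModel:
    if any(len(r) != 2 for r in rows):
        raise ValueError("position-weight file must have exactly 2 columns "
                         "(position, weight)")
    by_pos = {int(p): float(w) for p, w in rows}
    L = max(by_pos)
    if sorted(by_pos) != list(range(1, L + 1)):
        raise ValueError("position-weight file positions must be 1..L without gaps")
    return _pad_weights([by_pos[p] for p in range(1, L + 1)], guide_length, name)


def load_substitution_table(rows: list[list[str]], guide_length: int, name: str,
                            pam_rows: list[list[str]] | None = None,
                            default_factor: float | None = None,
                            ) -> SubstitutionScoreTable:
    if any(len(r) != 4 for r in rows):
        raise ValueError("substitution table must have 4 columns "
                         "(position, guide_base, genome_base, factor)")
    entries = {}
    L = 0
    for p, g, b, f in rows:
        entries[(int(p), g.upper(), b.upper())] = float(f)
        L = max(L, int(p))
    pad = guide_length - L
    if pad < 0:
        raise ValueError(f"guide_length {guide_length} shorter than table "
                         f"{name} ({L} positions)")
    if pad:
        # neutral factors at the PAM-distal start; shift table positions inward
        entries = {(p + pad, g, b): f for (p, g, b), f in entries.items()}
        for p in range(1, pad + 1):
            for g in "ACGT":
                for b in "ACGT":
                    if g != b:
                        entries[(p, g, b)] = 1.0
    pam_factors = tuple((m.upper(), float(f)) for m, f in (pam_rows or [("NNN", 1.0)]))
    return SubstitutionScoreTable(entries=entries, pam_factors=pam_factors,
                                  guide_length=guide_length, name=name,
                                  default_factor=default_factor)


def load_scoring_model(name_or_path: str, guide_length: int = 20, *,
                       pam_factor_path: str | None = None):
    """Load a builtin model by name or a user TSV by path.

    Builtins: ``hsu_zhang_2013`` (published position weights) and
    ``cfd_2016`` (CFD-shaped substitution table; packaged numbers are a
    labelled synthetic stand-in). A user file with 2 columns is read as
    position weights, with 4 columns as a substitution table (plus an
    optional PAM-factor file: mask TAB factor).
    """
    if name_or_path == "hsu_zhang_2013":
        rows = _parse_rows(_read_packaged("hsu_zhang_2013_weights.tsv"))
        return load_position_weights(rows, guide_length, "hsu_zhang_2013")
    if name_or_path == "cfd_2016":
        rows = _parse_rows(_read_packaged("cfd_table.synthetic.tsv"))
        pam_rows = _parse_rows(_read_packaged("cfd_pam.synthetic.tsv"))
        return load_substitution_table(rows, guide_length, "cfd_2016",
                                       pam_rows=pam_rows)
    with open(name_or_path) as fh:
        rows = _parse_rows(fh.read())
    if not rows:
        raise ValueError(f"empty scoring matrix {name_or_path}")
    pam_rows = None
    if pam_factor_path:
        with open(pam_factor_path) as fh:
            pam_rows = _parse_rows(fh.read())
    if len(rows[0]) == 2:
        return load_position_weights(rows, guide_length, name_or_path)
    return load_substitution_table(rows, guide_length, name_or_path,
                                   pam_rows=pam_rows)
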