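"""Readers and writers for SNPTEST v2 sample/GEN files, region lists and ID lists.

The sample file carries one individual per row with a header row of column
names and a second "type" row of codes: ``0`` (identifier/metadata), ``D``
(discrete covariate), ``C`` (continuous covariate), ``P`` (continuous
phenotype), ``B`` (binary phenotype).  The GEN file carries one variant per
row: five leading identifier fields followed by a probability triplet
(pAA, pAB, pBB) per individual.  Region files are whitespace-delimited with
three columns (name, start, end) or four (chromosome first).

Missing data conventions: the literal token ``NA`` marks a missing phenotype
value; a genotype probability triplet summing to less than
:data:`GEN_MISSING_SUM` (the GEN convention is to write ``0 0 0``) marks a
missing genotype.  Triplets whose sum lies in ``[GEN_MISSING_SUM, 1 +
GEN_RENORM_TOL]`` are renormalised to sum to one, tolerating imputation
rounding; larger sums are rejected as corrupt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

from .errors import ParseError, ValidationError

MISSING_TOKEN = "NA"
TYPE_CODES = frozenset({"0", "D", "C", "P", "B"})
PHENOTYPE_TYPE_CODES = frozenset({"C", "P", "B"})

#: probability-triplet sum below which a genotype is treated as missing
GEN_MISSING_SUM = 0.1
#: tolerated excess above 1.0 for a triplet sum before the line is rejected
GEN_RENORM_TOL = 0.02


def _open_text(source) -> tuple[IO[str], bool]:
    """Return (file object, needs_close) for a path or an open file object."""
    if hasattr(source, "read"):
        return source, False
    return open(source, "r"), True


# ---------------------------------------------------------------------------
# sample file


@dataclass
class PhenotypeTable:
    """Individuals-by-columns phenotype/covariate table from a sample file.

    ``values`` holds every column (including metadata columns) as float64
    with NaN as the missing marker; non-numeric entries of metadata (type
    ``0``/``D``) columns are stored as NaN.  Row order is authoritative: it
    indexes the genotype probability triplets in the paired GEN file.
    """

    individual_ids: list[str]
    column_names: list[str]
    column_types: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.column_names) != len(self.column_types):
            raise ValidationError("column_names and column_types differ in length")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            seen: set[str] = set()
            for iid in self.individual_ids:
                if iid in seen:
                    raise ValidationError(f"duplicate individual ID {iid!r}")
                seen.add(iid)
        for j, (name, code) in enumerate(zip(self.column_names, self.column_types)):
            if code == "B":
                col = self.values[:, j]
                ok = np.isnan(col) | (col == 0.0) | (col == 1.0)
                if not ok.all():
                    bad = col[~ok][0]
                    raise ValidationError(
                        f"binary column {name!r} contains value {bad!r}; "
                        "expected 0, 1 or missing"
                    )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def column_index(self, name: str) -> int:
        try:
            return self.column_names.index(name)
        except ValueError:
            raise KeyError(f"no column named {name!r} in sample file") from None

    def column_type(self, name: str) -> str:
        return self.column_types[self.column_index(name)]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_index(name)]

    def phenotype_matrix(self, names: Sequence[str]) -> np.ndarray:
        """Return an (n_individuals, K) matrix for the requested phenotypes.

        Each requested column must be typed C, P or B.
        """
        cols = []
        for name in names:
            code = self.column_type(name)
            if code not in PHENOTYPE_TYPE_CODES:
                raise ValidationError(
                    f"column {name!r} has type {code!r}; phenotypes must be "
                    "typed C, P or B"
                )
            cols.append(self.column(name))
        return np.column_stack(cols) if cols else np.empty((self.n_individuals, 0))


def read_sample_file(source) -> PhenotypeTable:
    """Parse a SNPTEST v2 sample file.

    The first line is the header, the second the type row (codes
    0/D/C/P/B), and each subsequent line one individual.  The first column
    is taken as the individual identifier.  ``NA`` values become NaN.
    """
    fh, needs_close = _open_text(source)
    try:
        header_line = fh.readline()
        if not header_line.strip():
            raise ParseError("sample file is empty or starts with a blank line")
        names = header_line.split()
        type_line = fh.readline()
        codes = type_line.split()
        if len(codes) != len(names):
            raise ParseError(
                f"type row (line 2) has {len(codes)} entries but the header "
                f"has {len(names)} columns"
            )
        for code in codes:
            if code not in TYPE_CODES:
                raise ParseError(
                    f"invalid column type code {code!r} on line 2; expected "
                    "one of 0, D, C, P, B"
                )

        ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=3):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != len(names):
                raise ParseError(
                    f"row {lineno - 2} (line {lineno}) has {len(tokens)} "
                    f"fields, expected {len(names)}"
                )
            ids.append(tokens[0])
            row = np.empty(len(names))
            row[0] = np.nan  # identifier column carries no numeric value
            for j in range(1, len(names)):
                tok = tokens[j]
                if tok == MISSING_TOKEN:
                    row[j] = np.nan
                    continue
                try:
                    row[j] = float(tok)
                except ValueError:
                    if codes[j] in PHENOTYPE_TYPE_CODES:
                        raise ParseError(
                            f"non-numeric value {tok!r} in column "
                            f"{names[j]!r} on line {lineno}"
                        ) from None
                    row[j] = np.nan  # string-valued metadata column
            rows.append(row)

        values = (
            np.vstack(rows) if rows else np.empty((0, len(names)))
        )
        return PhenotypeTable(ids, names, codes, values)
    finally:
        if needs_close:
            fh.close()


# ---------------------------------------------------------------------------
# GEN file


@dataclass
class VariantRecord:
    """One GEN-file variant with per-individual probability triplets.

    ``probs`` is an (N, 3) float array; missing genotypes are rows of NaN.
    Non-missing rows sum to one (renormalised at parse time).
    """

    snp_id: str
    rs_id: str
    position: int
    allele_a: str
    allele_b: str
    probs: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.probs[:, 0])


def normalize_triplets(raw: np.ndarray, context: str = "") -> np.ndarray:
    """Apply the missing/renormalisation convention to an (N, 3) triplet array.

    Sums below :data:`GEN_MISSING_SUM` become NaN rows; sums up to
    ``1 + GEN_RENORM_TOL`` are rescaled to one; anything larger raises.
    """
    if ((raw < 0) | (raw > 1)).any():
        bad = raw[(raw < 0) | (raw > 1)].flat[0]
        raise ValidationError(
            f"{context}genotype probability {bad!r} outside [0, 1]"
        )
    sums = raw.sum(axis=1)
    missing = sums < GEN_MISSING_SUM
    too_big = ~missing & (sums > 1.0 + GEN_RENORM_TOL)
    if too_big.any():
        raise ValidationError(
            f"{context}genotype probability triplet sums to "
            f"{sums[too_big][0]:.6g}; maximum allowed is {1.0 + GEN_RENORM_TOL}"
        )
    out = raw.astype(float, copy=True)
    with np.errstate(invalid="ignore"):
        out /= np.where(missing, np.nan, sums)[:, None]
    out[missing] = np.nan
    return out


def read_gen_stream(source, n_individuals: int) -> Iterator[VariantRecord]:
    """Stream variants from a SNPTEST v2 GEN file, one record at a time.

    Each line must carry ``5 + 3 * n_individuals`` whitespace-delimited
    fields; ``n_individuals`` comes from the paired sample file and is
    enforced on every line.
    """
    expected = 5 + 3 * n_individuals
    fh, needs_close = _open_text(source)
    try:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != expected:
                raise ParseError(
                    f"line {lineno}: expected {expected} fields "
                    f"(5 + 3×{n_individuals} individuals), got {len(tokens)}"
                )
            snp_id, rs_id, pos_tok, allele_a, allele_b = tokens[:5]
            try:
                position = int(pos_tok)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: non-integer position {pos_tok!r}"
                ) from None
            try:
                raw = np.array(tokens[5:], dtype=float).reshape(n_individuals, 3)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: non-numeric genotype probability"
                ) from None
            probs = normalize_triplets(raw, context=f"line {lineno}: ")
            yield VariantRecord(snp_id, rs_id, position, allele_a, allele_b, probs)
    finally:
        if needs_close:
            fh.close()


# ---------------------------------------------------------------------------
# regions and ID lists


@dataclass
class Region:
    """A named genomic interval; coordinates are 1-based and inclusive."""

    name: str
    start: int
    end: int
    chromosome: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("region name must be non-empty")
        if self.start > self.end:
            raise ValidationError(
                f"region {self.name!r}: start {self.start} exceeds end {self.end}"
            )

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def read_region_file(source) -> list[Region]:
    """Parse a region file: ``name start end`` or ``chrom name start end``."""
    fh, needs_close = _open_text(source)
    regions: list[Region] = []
    try:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) == 3:
                chrom, name, start_tok, end_tok = None, *tokens
            elif len(tokens) == 4:
                chrom, name, start_tok, end_tok = tokens
            else:
                raise ParseError(
                    f"line {lineno}: expected 3 or 4 columns, got {len(tokens)}"
                )
            try:
                start, end = int(start_tok), int(end_tok)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: non-integer region coordinate"
                ) from None
            regions.append(Region(name, start, end, chrom))
        return regions
    finally:
        if needs_close:
            fh.close()


def read_id_list(source) -> set[str]:
    """Read a one-identifier-per-line list; blank lines are ignored."""
    fh, needs_close = _open_text(source)
    try:
        return {line.strip() for line in fh if line.strip()}
    finally:
        if needs_close:
            fh.close()


# ---------------------------------------------------------------------------
# output files


@dataclass
class ResultRow:
    region_name: str
    start: int
    end: int
    n_variants_used: int
    n_individuals: int
    model_label: str
    log_likelihood: float | None
    bic: float | None
    p_value: float | None
    status: str = "ok"


@dataclass
class BetaRow:
    region_name: str
    model_label: str
    phenotype_name: str
    beta: float
    se: float


RESULT_HEADER = (
    "# region\tstart\tend\tn_variants\tn_individuals\tmodel\t"
    "loglik\tbic\tp_value\tstatus"
)
BETAS_HEADER = "# region\tmodel\tphenotype\tbeta\tse"


def _sci(x: float | None) -> str:
    return "NA" if x is None else f"{x:.6e}"


def write_outputs(
    prefix: str | Path,
    result_rows: Iterable[ResultRow],
    beta_rows: Iterable[BetaRow],
    log_lines: Iterable[str],
    error_lines: Iterable[str],
    write_betas: bool = False,
) -> None:
    """Write the ``.result``, ``.log``, ``.error`` (and optionally ``.betas``)
    files under ``prefix``.

    ``.error`` is created even on success, in which case it is empty.
    Numeric columns use scientific notation with six significant digits.
    """
    prefix = str(prefix)
    with open(prefix + ".result", "w") as fh:
        fh.write(RESULT_HEADER + "\n")
        for row in result_rows:
            fh.write(
                "\t".join(
                    [
                        row.region_name,
                        str(row.start),
                        str(row.end),
                        str(row.n_variants_used),
                        str(row.n_individuals),
                        row.model_label or "NA",
                        _sci(row.log_likelihood),
                        _sci(row.bic),
                        _sci(row.p_value),
                        row.status,
                    ]
                )
                + "\n"
            )
    if write_betas:
        with open(prefix + ".betas", "w") as fh:
            fh.write(BETAS_HEADER + "\n")
            for brow in beta_rows:
                fh.write(
                    "\t".join(
                        [
                            brow.region_name,
                            brow.model_label,
                            brow.phenotype_name,
                            _sci(brow.beta),
                            _sci(brow.se),
                        ]
                    )
                    + "\n"
                )
    with open(prefix + ".log", "w") as fh:
        for line in log_lines:
            fh.write(line.rstrip("\n") + "\n")
    with open(prefix + ".error", "w") as fh:
        for line in error_lines:
            fh.write(line.rstrip("\n") + "\n")
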