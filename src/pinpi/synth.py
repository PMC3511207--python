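"""Synthetic Pin-II precursor libraries with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a pool of unique ~50-aa IRDs built on the eight-cysteine scaffold, each
  carrying one reactive-site pentapeptide drawn from the naturally
  observed motif set (TI: CPRNC/CPKNC/CPRYC/CPRDC; CI: CTLNC/CTPNC), with
  sequence variation concentrated in the reactive-site loop and towards
  the C-terminal end, plus a configurable number of cysteine variants;
* precursor genes assembled as a 25-residue signal peptide followed by
  alternating linkers and 1-4 pool IRDs (genes share pool IRDs exactly,
  as the natural gene family does);
* clone libraries drawn multinomially per treatment with the study's
  sequencing depths (25 uninduced, 60 per induced treatment);
* peak lists of fully oxidized single-IRD masses with Gaussian noise.

One integer seed drives a single ``numpy.random.Generator`` passed through
every stochastic step, so each artifact is exactly reproducible.  Body
residues are drawn uniformly from the 19 non-cysteine letters (cysteines
appear only where the scaffold or an explicit cysteine-variant mechanism
puts them, keeping the reactive-site anchor unambiguous); linkers share
one canonical sequence per run, truncated per site, mirroring the
conserved protease-target propeptides of natural precursors.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import STANDARD_AA, ValidationError
from .annotate import AnnotationConfig, PrecursorSequence
from .diversity import CloneCountTable
from .massmatch import PeakList, PeptideCandidate, average_mass

__all__ = [
    "SyntheticConfig",
    "IRDPoolEntry",
    "SyntheticDataset",
    "generate_ird_pool",
    "generate_sp_pool",
    "generate_precursors",
    "generate_clone_table",
    "generate_peaklist",
    "mutate_outside_anchors",
    "simulate",
]

TI_MOTIFS = ("CPRNC", "CPKNC", "CPRYC", "CPRDC")
CI_MOTIFS = ("CTLNC", "CTPNC")

#: Residues used for bodies and linkers: everything but cysteine.
BODY_ALPHABET = STANDARD_AA.replace("C", "")


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator.

    Defaults mirror the study conditions: a 28-IRD pool with a 21:7
    trypsin:chymotrypsin split and four cysteine variants, 47 genes with
    the observed 1/2/3/4-domain architecture mix, ten signal-peptide
    variants, and clone totals of 25 (uninduced) / 60 (induced).
    """

    seed: int = 0
    n_unique_irds: int = 28
    ti_fraction: float = 21 / 28
    n_cys_variants: int = 4
    ird_length: int = 50
    ird_length_jitter: int = 4
    cys_template: tuple[int, ...] = AnnotationConfig.cys_template
    rs_template_index: int = AnnotationConfig.rs_template_index
    n_genes: int = 47
    architecture_probs: tuple[tuple[int, float], ...] = (
        (1, 3 / 47),
        (2, 15 / 47),
        (3, 20 / 47),
        (4, 9 / 47),
    )
    sp_pool_size: int = 10
    sp_length: int = 25
    linker_length: tuple[int, int] = (4, 12)
    mutation_rate: float = 0.0
    treatments: tuple[str, ...] = ("UL", "AI", "W+W", "W+OS")
    clone_totals: tuple[tuple[str, int], ...] = (
        ("UL", 25),
        ("AI", 60),
        ("W+W", 60),
        ("W+OS", 60),
    )
    gene_proportions: Optional[dict[str, Sequence[float]]] = None
    n_peaks: int = 8
    peak_noise_sd: float = 0.5
    min_mass_separation: float = 10.0

    @property
    def tail_length(self) -> int:
        return self.ird_length - self.cys_template[-1] - 1

    def validate(self) -> None:
        t = self.cys_template
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError("cysteine template must be strictly increasing")
        if self.tail_length < 1:
            raise ValidationError(
                f"cysteine template (last offset {t[-1]}) does not fit an "
                f"IRD of {self.ird_length} residues"
            )
        rs = self.rs_template_index
        if t[rs + 1] - t[rs] != 4:
            raise ValidationError("reactive-site cysteines must be 4 residues apart")
        probs = dict(self.architecture_probs)
        if abs(sum(probs.values()) - 1) > 1e-9 or any(p < 0 for p in probs.values()):
            raise ValidationError("architecture probabilities must form a distribution")
        if not 0 <= self.ti_fraction <= 1:
            raise ValidationError("ti_fraction must be in [0, 1]")
        if self.n_cys_variants > self.n_unique_irds:
            raise ValidationError("more cysteine variants than pool entries")

    def annotation_config(self) -> AnnotationConfig:
        return AnnotationConfig(
            sp_length=self.sp_length,
            cys_template=self.cys_template,
            rs_template_index=self.rs_template_index,
            tail_length=self.tail_length,
            end_search=max(AnnotationConfig.end_search, self.ird_length_jitter),
        )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class IRDPoolEntry:
    label: int
    aa_seq: str
    inhibitor_class: str
    motif: str
    is_cys_variant: bool


@dataclass
class SyntheticDataset:
    """Everything one simulation run produced, plus its ground truth."""

    config: SyntheticConfig
    pool: list[IRDPoolEntry]
    sp_pool: list[str]
    precursors: list[PrecursorSequence]
    truth: dict
    clone_table: CloneCountTable
    peaks: PeakList

    def truth_json(self) -> dict:
        out = dict(self.truth)
        out["config"] = asdict(self.config)
        return out


def _choice(rng: np.random.Generator, alphabet: str, size: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=size))


def _scrub_spurious_motifs(seq: list[str], cys_positions: set[int], rs_start: int) -> None:
    """Destroy accidental C-[P/T]-X-X-C motifs other than the reactive site.

    For every cysteine pair four residues apart that is not the reactive
    site, a P or T directly after the first cysteine is replaced, so the
    pentapeptide anchor stays unique within the domain.
    """
    for p in sorted(cys_positions):
        if p == rs_start:
            continue
        if p + 4 in cys_positions and p + 1 < len(seq) and seq[p + 1] in "PT":
            seq[p + 1] = "A"


def _draw_canonical_body(
    config: SyntheticConfig, rng: np.random.Generator, max_len: int
) -> str:
    """Random canonical scaffold body, redrawn until a nominal-length
    domain weighs what a natural single-IRD peptide does (~114-118 Da per
    residue), so simulated processed-peptide masses fall in the 5.5-6.3
    kDa band observed for this family."""
    from .massmatch import average_mass

    lo, hi = 114.0 * config.ird_length, 118.0 * config.ird_length
    body = _choice(rng, BODY_ALPHABET, max_len)
    for _ in range(2000):
        if lo <= average_mass(body[: config.ird_length]) <= hi:
            return body
        body = _choice(rng, BODY_ALPHABET, max_len)
    return body  # pragma: no cover - vanishingly unlikely


def _draw_offsets(config: SyntheticConfig, rng: np.random.Generator) -> tuple[int, ...]:
    """Per-entry scaffold offsets: small jitter on the interior cysteines,
    larger C-terminal jitter on the last one; anchor cysteines fixed."""
    t = list(config.cys_template)
    rs = config.rs_template_index
    j = config.ird_length_jitter
    for _ in range(100):
        offs = list(t)
        for i in range(1, len(t) - 1):
            if i in (rs, rs + 1):
                continue
            hi = 1 if t[i + 1] - t[i] > 5 else 0  # never shrink a gap to 4
            offs[i] = t[i] + int(rng.integers(-1, hi + 1))
        offs[-1] = t[-1] + int(rng.integers(-j, j + 1))
        gaps = [b - a for a, b in zip(offs, offs[1:])]
        if all(g >= 2 for g in gaps) and all(
            g != 4 for i, g in enumerate(gaps) if i != rs
        ):
            return tuple(offs)
    raise ValidationError("could not draw a feasible cysteine layout; template too tight")


def generate_ird_pool(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> list[IRDPoolEntry]:
    """A pool of unique labeled IRD sequences with known classes.

    ``round(ti_fraction * n)`` entries are trypsin-inhibitory, the rest
    chymotrypsin-inhibitory; the first ``n_cys_variants`` entries of each
    class rotation carry a scaffold defect (a cysteine removed, moved
    beyond tolerance, or added).  Entries derive from one canonical body
    with mutations weighted towards the reactive-site loop and the
    C-terminal tail, so pool members are similar but never identical.
    """
    config.validate()
    if rng is None:
        rng = config.rng()
    n = config.n_unique_irds
    n_ti = int(round(config.ti_fraction * n))
    classes = ["TI"] * n_ti + ["CI"] * (n - n_ti)
    # spread the cysteine variants over both classes deterministically
    variant_idx = set(np.linspace(0, n - 1, config.n_cys_variants, dtype=int).tolist()) if config.n_cys_variants else set()
    rs = config.rs_template_index
    rs_start_tpl = config.cys_template[rs]

    max_len = config.ird_length + config.ird_length_jitter
    canonical_body = _draw_canonical_body(config, rng, max_len)

    entries: list[IRDPoolEntry] = []
    seen: set[str] = set()
    masses: list[float] = []
    for i, cls in enumerate(classes):
        for _attempt in range(500):
            offs = _draw_offsets(config, rng)
            length = offs[-1] + 1 + config.tail_length
            seq = list(canonical_body[:length])
            # position-weighted diversification: loop + C-terminal bias
            loop = range(config.cys_template[rs] - 4, config.cys_template[rs + 1] + 6)
            weights = np.ones(length)
            weights[[p for p in loop if p < length]] = 3.0
            weights[offs[-1] - 4 :] = 3.0
            n_mut = 1 + rng.poisson(4)
            probs = weights / weights.sum()
            for p in rng.choice(length, size=min(n_mut, length), replace=False, p=probs):
                seq[p] = BODY_ALPHABET[rng.integers(0, len(BODY_ALPHABET))]
            for off in offs:
                seq[off] = "C"
            motif = (TI_MOTIFS if cls == "TI" else CI_MOTIFS)[
                rng.integers(0, 4 if cls == "TI" else 2)
            ]
            rs_start = offs[rs]
            seq[rs_start : rs_start + 5] = list(motif)
            cys_pos = set(offs)
            is_variant = i in variant_idx
            if is_variant:
                cys_pos = _apply_cys_variant(seq, offs, config.cys_template, rs, rng)
            _scrub_spurious_motifs(seq, cys_pos, rs_start)
            s = "".join(seq)
            # pool members are kept mass-resolvable, as the natural
            # processed species observed by MALDI are
            mass = average_mass(s)
            if s not in seen and all(
                abs(mass - m) >= config.min_mass_separation for m in masses
            ):
                seen.add(s)
                masses.append(mass)
                entries.append(
                    IRDPoolEntry(
                        label=i + 1,
                        aa_seq=s,
                        inhibitor_class=cls,
                        motif=motif,
                        is_cys_variant=is_variant,
                    )
                )
                break
        else:  # pragma: no cover - would need absurd collision rates
            raise ValidationError("failed to draw a unique pool sequence")
    return entries


def _apply_cys_variant(
    seq: list[str],
    offs: tuple[int, ...],
    template: Sequence[int],
    rs: int,
    rng: np.random.Generator,
) -> set[int]:
    """Mutate the scaffold: delete, move, or add one cysteine.

    Never touches the first, last, or reactive-site cysteines, so the
    anchor and the domain boundaries stay recoverable.  A moved cysteine
    always ends up well beyond the spacing tolerance of its template
    position, so the variant is detectable.
    """
    movable = [i for i in range(1, len(offs) - 1) if i not in (rs, rs + 1)]
    mech = rng.integers(0, 3)
    cys = set(offs)
    if mech == 0:  # delete
        i = movable[rng.integers(0, len(movable))]
        seq[offs[i]] = "S"
        cys.discard(offs[i])
    elif mech == 1:  # move beyond tolerance
        for _ in range(200):
            i = movable[rng.integers(0, len(movable))]
            shift = int(rng.choice([-5, -4, 4, 5]))
            new = offs[i] + shift
            if (
                1 <= new < offs[-1] - 1
                and abs(new - template[i]) >= 4
                and all(abs(new - c) >= 2 for c in cys if c != offs[i])
            ):
                seq[offs[i]] = "S"
                seq[new] = "C"
                cys.discard(offs[i])
                cys.add(new)
                return cys
        # fall back to deletion when no legal move exists
        i = movable[rng.integers(0, len(movable))]
        seq[offs[i]] = "S"
        cys.discard(offs[i])
    else:  # add an extra cysteine in the body
        for _ in range(200):
            new = int(rng.integers(1, offs[-1] - 2))
            if all(abs(new - c) >= 3 for c in cys):
                seq[new] = "C"
                cys.add(new)
                break
    return cys


def generate_sp_pool(config: SyntheticConfig, rng: Optional[np.random.Generator] = None) -> list[str]:
    """Unique signal-peptide sequences: Met start, random body."""
    if rng is None:
        rng = config.rng()
    pool: list[str] = []
    seen: set[str] = set()
    while len(pool) < config.sp_pool_size:
        sp = "M" + _choice(rng, BODY_ALPHABET, config.sp_length - 1)
        if sp not in seen:
            seen.add(sp)
            pool.append(sp)
    return pool


def mutate_outside_anchors(
    aa_seq: str,
    protected: set[int],
    rng: np.random.Generator,
    *,
    rate: Optional[float] = None,
    k: Optional[int] = None,
) -> str:
    """Substitute residues outside the protected positions.

    Either a per-residue ``rate`` or an exact count ``k`` of substitutions.
    Replacements come from the non-cysteine alphabet and always differ
    from the original residue.
    """
    seq = list(aa_seq)
    free = [i for i in range(len(seq)) if i not in protected]
    if k is not None:
        targets = rng.choice(len(free), size=min(k, len(free)), replace=False)
        targets = [free[int(t)] for t in np.atleast_1d(targets)]
    else:
        targets = [i for i in free if rng.random() < (rate or 0.0)]
    for i in targets:
        choices = [a for a in BODY_ALPHABET if a != seq[i]]
        seq[i] = choices[rng.integers(0, len(choices))]
    return "".join(seq)


def generate_precursors(
    pool: list[IRDPoolEntry],
    config: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
    sp_pool: Optional[list[str]] = None,
) -> tuple[list[PrecursorSequence], dict]:
    """Assemble genes (SP + alternating linkers and pool IRDs) with ground truth.

    Ground truth records, per gene, every segment's coordinates, the IRD
    labels and classes, and the architecture; substitution noise (at
    ``mutation_rate``) never touches scaffold cysteines or reactive
    sites, so the recorded boundaries stay valid.
    """
    if not pool:
        raise ValidationError("IRD pool is empty")
    config.validate()
    if rng is None:
        rng = config.rng()
    if sp_pool is None:
        sp_pool = generate_sp_pool(config, rng)
    ks, probs = zip(*config.architecture_probs)
    lmin, lmax = config.linker_length
    # linkers are conserved protease-target propeptides: one canonical
    # linker per run, truncated to a per-site random length
    canonical_linker = _choice(rng, BODY_ALPHABET, max(lmax, 1))
    by_label = {e.label: e for e in pool}
    records: list[PrecursorSequence] = []
    truth_genes = []
    for g in range(config.n_genes):
        gene_id = f"SYN-{g + 1}"
        k = int(rng.choice(ks, p=probs))
        labels = [int(pool[rng.integers(0, len(pool))].label) for _ in range(k)]
        sp_idx = int(rng.integers(0, len(sp_pool)))
        parts: list[str] = [sp_pool[sp_idx]]
        segments = [
            {"type": "signal_peptide", "start": 0, "end": config.sp_length, "label": sp_idx + 1}
        ]
        pos = config.sp_length
        protected: set[int] = set()
        for j, lab in enumerate(labels):
            linker = canonical_linker[: int(rng.integers(lmin, lmax + 1))]
            parts.append(linker)
            segments.append({"type": "linker", "start": pos, "end": pos + len(linker)})
            pos += len(linker)
            entry = by_label[lab]
            parts.append(entry.aa_seq)
            start, end = pos, pos + len(entry.aa_seq)
            segments.append(
                {
                    "type": "ird",
                    "start": start,
                    "end": end,
                    "label": lab,
                    "class": entry.inhibitor_class,
                    "is_cys_variant": entry.is_cys_variant,
                }
            )
            protected.update(start + i for i, a in enumerate(entry.aa_seq) if a == "C")
            rs_abs = start + entry.aa_seq.index(entry.motif)
            protected.update(range(rs_abs, rs_abs + 5))
            pos = end
        terminal = canonical_linker[: int(rng.integers(lmin, lmax + 1))]
        parts.append(terminal)
        segments.append({"type": "linker", "start": pos, "end": pos + len(terminal)})
        pos += len(terminal)
        seq = "".join(parts)
        assert len(seq) == pos
        if config.mutation_rate > 0:
            seq = mutate_outside_anchors(seq, protected, rng, rate=config.mutation_rate)
        records.append(PrecursorSequence(id=gene_id, aa_seq=seq))
        truth_genes.append(
            {
                "gene_id": gene_id,
                "n_irds": k,
                "sp_label": sp_idx + 1,
                "ird_labels": labels,
                "segments": segments,
            }
        )
    truth = {
        "genes": truth_genes,
        "pool": {
            e.label: {
                "aa_seq": e.aa_seq,
                "class": e.inhibitor_class,
                "is_cys_variant": e.is_cys_variant,
            }
            for e in pool
        },
    }
    return records, truth


def generate_clone_table(
    config: SyntheticConfig,
    gene_ids: Sequence[str],
    rng: Optional[np.random.Generator] = None,
) -> tuple[CloneCountTable, dict]:
    """Multinomial clone counts per treatment at the study's sequencing depths.

    Per-treatment gene proportions come from the config or, by default,
    a flat Dirichlet draw.  Column sums always equal the configured totals.
    """
    config.validate()
    if rng is None:
        rng = config.rng()
    totals = dict(config.clone_totals)
    n = len(gene_ids)
    proportions: dict[str, np.ndarray] = {}
    counts = {}
    for t in config.treatments:
        if config.gene_proportions is not None:
            p = np.asarray(config.gene_proportions[t], dtype=float)
            if p.shape != (n,) or abs(p.sum() - 1) > 1e-9 or (p < 0).any():
                raise ValidationError(f"invalid proportion vector for {t!r}")
        else:
            p = rng.dirichlet(np.ones(n))
        proportions[t] = p
        counts[t] = rng.multinomial(totals[t], p)
    df = pd.DataFrame(counts, index=list(gene_ids))
    table = CloneCountTable(counts=df, expected_totals=totals)
    truth = {"proportions": {t: proportions[t].tolist() for t in config.treatments}}
    return table, truth


def generate_peaklist(
    candidates: Sequence[PeptideCandidate],
    config: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[PeakList, list[PeptideCandidate]]:
    """Noisy oxidized masses of randomly chosen processed peptides.

    Returns the peak list and, aligned with its sorted values, the true
    source candidate of each peak.
    """
    if not candidates:
        raise ValidationError("no candidates to draw peaks from")
    if rng is None:
        rng = config.rng()
    n = min(config.n_peaks, len(candidates))
    idx = rng.choice(len(candidates), size=n, replace=False)
    chosen = [candidates[int(i)] for i in idx]
    values = [c.mass_oxidized + rng.normal(0.0, config.peak_noise_sd) if config.peak_noise_sd else c.mass_oxidized for c in chosen]
    order = np.argsort(values)
    peaks = PeakList(values=[values[int(i)] for i in order])
    sources = [chosen[int(i)] for i in order]
    return peaks, sources


def simulate(config: SyntheticConfig) -> SyntheticDataset:
    """Run the full generator once: pool, genes, clone table, peaks."""
    from .annotate import annotate_precursor
    from .massmatch import enumerate_candidates

    rng = config.rng()
    pool = generate_ird_pool(config, rng)
    sp_pool = generate_sp_pool(config, rng)
    precursors, truth = generate_precursors(pool, config, rng, sp_pool)
    table, prop_truth = generate_clone_table(config, [p.id for p in precursors], rng)
    truth.update(prop_truth)
    acfg = config.annotation_config()
    candidates = []
    for rec in precursors:
        ann = annotate_precursor(rec, acfg)
        candidates.extend(enumerate_candidates(ann))
    peaks, sources = generate_peaklist(candidates, config, rng)
    truth["peak_sources"] = [
        {"peak": p, "gene_id": c.gene_id, "aa_seq": c.aa_seq, "mass": c.mass_oxidized}
        for p, c in zip(peaks.values, sources)
    ]
    return SyntheticDataset(
        config=config,
        pool=pool,
        sp_pool=sp_pool,
        precursors=precursors,
        truth=truth,
        clone_table=table,
        peaks=peaks,
    )
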