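"""Seeded generators emulating the data classes every pipeline stage
consumes, so the whole pipeline is testable without downloads.

Three generators, all pure functions of a :class:`SimSpec` (same spec,
same bytes):

* hairpin precursor families with a planted mature strand on a known
  arm and point mutations that preferentially preserve pairability
  (so simulated families still fold);
* degradome profiles with Poisson background counts and spiked read
  peaks at the slice positions of planted, perfectly complementary
  target sites;
* qPCR Ct tables over the full tissue x treatment x timepoint design
  with known planted log2 fold-changes.

Every generator also emits a truth table sufficient to score the
downstream stage without re-reading generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import Arm, MirSeqRecord, SeqKind, reverse_complement

BASES = np.array(list("ACGU"))

#: canonical deeply-conserved plant miR166 3p mature sequence, used as
#: the simulation ancestor so family statistics (length, composition,
#: conserved 9G/11C/12U/16U positions) look like the real family
CANONICAL_MIR166_3P = "UCGGACCAGGCUUCAUUCCCC"

TISSUES = ("root", "leaf")
TREATMENTS = ("PEG", "SNP", "PTIO")
TIMEPOINTS = (0.0, 6.0, 12.0, 24.0)


@dataclass
class SimSpec:
    """Parameters of the synthetic study.

    Defaults mirror the real study design: 4 precursors / 8 matures of
    ~21 nt, a 3 x 2 x 4 (treatment x tissue x timepoint) qPCR design
    with 3 biological x 3 technical replicates, sparse degradome
    background (lambda = 1 read/position on ~1 kb transcripts) with
    ~50-fold cleavage spikes.
    """

    seed: int = 0
    # precursor family
    n_precursors: int = 4
    stem_length: int = 35
    loop_length: int = 8
    mature_length: int = 21
    mutation_rate: float = 0.05
    # degradome
    n_transcripts: int = 100
    n_planted_targets: int = 20
    transcript_length: int = 1000
    background_lambda: float = 1.0
    spike_multiplier: float = 50.0
    # qPCR
    ct_noise_sd: float = 0.1
    n_bio_reps: int = 3
    n_tech_reps: int = 3
    reference_ct: float = 20.0
    target_baseline_ct: float = 5.0
    genes: tuple[str, ...] = ("miR166a", "miR166b", "miR166c")
    planted_log2fc: float | dict = 2.0

    def __post_init__(self) -> None:
        if min(self.n_precursors, self.stem_length, self.loop_length,
               self.mature_length, self.n_transcripts, self.transcript_length,
               self.n_bio_reps, self.n_tech_reps) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.stem_length < self.mature_length:
            raise ValueError("stem must be at least as long as the mature strand")
        if self.loop_length < 3:
            raise ValueError("terminal loop must be >= 3 nt")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def _random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


# ---------------------------------------------------------------------------
# Precursor families
# ---------------------------------------------------------------------------

_PAIR_PRESERVING = {
    # substitution that keeps the base pairable with its partner
    # (turns a Watson-Crick pair into a G:U wobble)
    "C": "U",  # G:C -> G:U
    "A": "G",  # A:U -> G:U
}


def gen_precursor_family(spec: SimSpec) -> tuple[list[MirSeqRecord], pd.DataFrame]:
    """Simulate a hairpin precursor family with planted mature arms.

    Each precursor is 5' arm + terminal loop + reverse-complemented 5'
    arm; point mutations hit each position independently at
    ``mutation_rate`` and, 2:1, favour substitutions that keep the
    mutated base pairable with its partner (G:U-forming transitions),
    so mutated precursors still fold into hairpins.  The mature strand
    is read off the finished precursor on an alternating arm, so it is
    always an exact substring.

    Returns the precursor records and a truth table (precursor_id,
    mature_id, mature_seq, arm, start, end; 1-based inclusive).
    """
    rng = spec.rng(stream=1)
    ancestor_arm = _plant_mature(
        _random_rna(rng, spec.stem_length), CANONICAL_MIR166_3P[: spec.mature_length], rng
    )
    if spec.mature_length > len(CANONICAL_MIR166_3P):
        ancestor_arm = _plant_mature(
            _random_rna(rng, spec.stem_length), _random_rna(rng, spec.mature_length), rng
        )
    precursors: list[MirSeqRecord] = []
    truth_rows = []
    for k in range(spec.n_precursors):
        arm5 = _mutate(ancestor_arm, spec.mutation_rate, rng)
        arm3 = reverse_complement(arm5)
        arm3 = _mutate(arm3, spec.mutation_rate, rng)
        loop = _random_rna(rng, spec.loop_length)
        seq = arm5 + loop + arm3
        pre_id = f"sim-pre-miR166{chr(ord('a') + k)}"
        precursors.append(
            MirSeqRecord(id=pre_id, sequence=seq, species_code="sim",
                         kind=SeqKind.PRECURSOR)
        )
        arm = Arm.FIVE_PRIME if k % 2 == 0 else Arm.THREE_PRIME
        pos = _mature_position(spec, len(seq), arm)
        mature_seq = seq[pos - 1: pos - 1 + spec.mature_length]
        truth_rows.append(
            {
                "precursor_id": pre_id,
                "mature_id": f"sim-miR166{chr(ord('a') + k)}-{arm.value}",
                "mature_seq": mature_seq,
                "arm": arm.value,
                "start": pos,
                "end": pos + spec.mature_length - 1,
            }
        )
    return precursors, pd.DataFrame(truth_rows)


def _plant_mature(arm: str, mature: str, rng: np.random.Generator) -> str:
    offset = int(rng.integers(0, len(arm) - len(mature) + 1))
    return arm[:offset] + mature + arm[offset + len(mature):]


def _mature_position(spec: SimSpec, total_len: int, arm: Arm) -> int:
    """1-based start so the mature sits wholly on the requested arm,
    flush against the outer end of the stem."""
    if arm is Arm.FIVE_PRIME:
        return 1
    return total_len - spec.mature_length + 1


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hits = np.where(rng.random(len(seq)) < rate)[0]
    for i in hits:
        base = out[i]
        preserving = _PAIR_PRESERVING.get(base)
        if preserving is not None and rng.random() < 2.0 / 3.0:
            out[i] = preserving
        else:
            choices = [b for b in "ACGU" if b != base]
            out[i] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def gen_mature_family(
    spec: SimSpec, n: int = 8, mutation_rate: float | None = None
) -> list[MirSeqRecord]:
    """A family of mature-strand records: copies of the canonical
    miR166 3p sequence with independent per-site mutations (rate
    defaults to ``spec.mutation_rate``)."""
    rng = spec.rng(stream=4)
    rate = spec.mutation_rate if mutation_rate is None else mutation_rate
    base = CANONICAL_MIR166_3P[: spec.mature_length]
    if spec.mature_length > len(CANONICAL_MIR166_3P):
        base = _random_rna(rng, spec.mature_length)
    return [
        MirSeqRecord(
            id=f"sim-miR166-{k}",
            sequence=_mutate(base, rate, rng),
            species_code="sim",
        )
        for k in range(n)
    ]


# ---------------------------------------------------------------------------
# Degradome
# ---------------------------------------------------------------------------

def gen_degradome(
    spec: SimSpec,
    mirnas: list[MirSeqRecord] | None = None,
) -> tuple[list[MirSeqRecord], list[MirSeqRecord], list["DegradomeProfile"], pd.DataFrame]:
    """Simulate miRNAs, transcripts, degradome profiles and a truth table.

    ``n_planted_targets`` transcripts receive a perfectly
    complementary site for one of the miRNAs and a read spike of
    Poisson(spike_multiplier x background_lambda) at the site's slice
    position; the rest are decoys.  All transcripts get
    Poisson(background_lambda) background counts per position.
    """
    from .degradome import DegradomeProfile

    rng = spec.rng(stream=2)
    if mirnas is None:
        mirnas = gen_mature_family(spec, n=3, mutation_rate=0.0)
        # distinct ids but distinct sequences too, to avoid ambiguous truth
        mirnas = [
            MirSeqRecord(id=f"sim-miR166-{k}", sequence=_mutate(
                mirnas[0].sequence, 0.10, rng) if k else mirnas[0].sequence,
                species_code="sim")
            for k in range(3)
        ]
    if spec.n_planted_targets > spec.n_transcripts:
        raise ValueError("more planted targets than transcripts")
    transcripts: list[MirSeqRecord] = []
    profiles: list[DegradomeProfile] = []
    truth_rows = []
    L = len(mirnas[0].sequence)
    for t in range(spec.n_transcripts):
        tid = f"sim-tx{t:04d}"
        seq = _random_rna(rng, spec.transcript_length)
        counts = rng.poisson(spec.background_lambda, size=spec.transcript_length)
        if t < spec.n_planted_targets:
            mir = mirnas[t % len(mirnas)]
            site_start = int(rng.integers(1, spec.transcript_length - L + 2))
            site = reverse_complement(mir.sequence)
            seq = seq[: site_start - 1] + site + seq[site_start - 1 + L:]
            t_slice = site_start + L - 10
            spike = int(rng.poisson(spec.spike_multiplier * max(spec.background_lambda, 1e-9)))
            counts[t_slice - 1] += spike
            truth_rows.append(
                {
                    "mirna_id": mir.id,
                    "transcript_id": tid,
                    "site_start": site_start,
                    "site_end": site_start + L - 1,
                    "t_slice": t_slice,
                    "spike": spike,
                }
            )
        transcripts.append(MirSeqRecord(id=tid, sequence=seq, species_code="sim"))
        profiles.append(DegradomeProfile(transcript_id=tid, counts=counts))
    return mirnas, transcripts, profiles, pd.DataFrame(
        truth_rows,
        columns=["mirna_id", "transcript_id", "site_start", "site_end",
                 "t_slice", "spike"],
    )


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def gen_ct_table(spec: SimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full-factorial qPCR Ct table with known effects.

    For every gene x tissue x treatment x timepoint, the planted log2
    fold-change relative to the 0 h calibrator shifts the target Ct
    down by that many cycles; each technical measurement adds Gaussian
    noise of ``ct_noise_sd`` cycles.  ``planted_log2fc`` may be a
    single float (applied at every non-calibrator timepoint) or a dict
    keyed (gene, tissue, treatment, timepoint).

    Returns (ct table, truth table of planted log2fc per condition).
    """
    rng = spec.rng(stream=3)
    rows = []
    truth_rows = []
    for tissue in TISSUES:
        ref_gene = "U6"
        for treatment in TREATMENTS:
            for tp in TIMEPOINTS:
                for gene in spec.genes:
                    fc = _planted_fc(spec, gene, tissue, treatment, tp)
                    truth_rows.append(
                        {"gene_id": gene, "tissue": tissue, "treatment": treatment,
                         "timepoint_h": tp, "log2fc": fc}
                    )
                for bio in range(1, spec.n_bio_reps + 1):
                    for tech in range(1, spec.n_tech_reps + 1):
                        ref_ct = spec.reference_ct + rng.normal(0.0, spec.ct_noise_sd)
                        rows.append(
                            {"tissue": tissue, "treatment": treatment,
                             "timepoint_h": tp, "gene_id": ref_gene,
                             "gene_class": "reference", "bio_rep": bio,
                             "tech_rep": tech, "ct": ref_ct}
                        )
                        for gene in spec.genes:
                            fc = _planted_fc(spec, gene, tissue, treatment, tp)
                            ct = (
                                spec.reference_ct + spec.target_baseline_ct - fc
                                + rng.normal(0.0, spec.ct_noise_sd)
                            )
                            rows.append(
                                {"tissue": tissue, "treatment": treatment,
                                 "timepoint_h": tp, "gene_id": gene,
                                 "gene_class": "mirna", "bio_rep": bio,
                                 "tech_rep": tech, "ct": ct}
                            )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def _planted_fc(spec: SimSpec, gene, tissue, treatment, timepoint) -> float:
    if timepoint == 0.0:
        return 0.0
    if isinstance(spec.planted_log2fc, dict):
        return float(spec.planted_log2fc.get((gene, tissue, treatment, timepoint), 0.0))
    return float(spec.planted_log2fc)
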