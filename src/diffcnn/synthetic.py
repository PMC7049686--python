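"""Synthetic differential TF-binding datasets with known ground truth.

The generator emulates the structure of a multi-tissue differential ChIP-seq
study of an anchor TF whose occupancy is modulated by tissue-specific
co-factors:

* every region carries one anchor-TF motif instance (binding happens
  everywhere);
* regions destined for a differential class additionally carry one
  co-factor motif whose activity pattern (the set of tissues in which the
  co-factor is expressed) determines which tissue gains or loses occupancy;
* per-replicate RPKM values are the product of a region-level baseline, the
  co-factor's multiplicative effect in tissues where it is active, and
  log-normal replicate noise;
* class labels are re-derived from the simulated RPKM by a mean
  fold-change threshold rule — a simplified stand-in for the count-based
  differential test used on real data, with the same class semantics
  (up in one tissue, down in one tissue, non-differential);
* two replicates of validation reads are concentrated around planted
  co-factor sites on top of a uniform background, emulating independent
  ChIP-seq of the co-factor itself.

Every region is written as its own contig, so region-relative and genomic
coordinates coincide and all downstream coordinate logic is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import BASES, one_hot_encode

__all__ = [
    "MotifModel",
    "SimulationConfig",
    "SimRegion",
    "SyntheticDataset",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "default_cofactor_motifs",
]


@dataclass
class MotifModel:
    """A position weight matrix over A, C, G, T with its consensus string."""

    name: str
    pwm: np.ndarray  # (4, W) per-position base probabilities
    consensus: str

    def __post_init__(self):
        self.pwm = np.asarray(self.pwm, dtype=np.float64)
        W = self.pwm.shape[1]
        if not 6 <= W <= 12:
            raise ValueError(f"motif width must be in [6, 12], got {W}")
        if not np.allclose(self.pwm.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        argmax = "".join(BASES[i] for i in self.pwm.argmax(axis=0))
        if argmax != self.consensus:
            raise ValueError(f"consensus {self.consensus!r} is not the per-column argmax")

    @property
    def width(self) -> int:
        return self.pwm.shape[1]

    @classmethod
    def from_consensus(cls, name: str, consensus: str, strength: float = 0.98) -> "MotifModel":
        """Build a PWM that places ``strength`` probability on the consensus
        base at each position and spreads the rest evenly."""
        consensus = consensus.upper()
        W = len(consensus)
        pwm = np.full((4, W), (1.0 - strength) / 3.0)
        for i, base in enumerate(consensus):
            pwm[BASES.index(base), i] = strength
        return cls(name, pwm, consensus)

    def sample(self, rng: np.random.Generator) -> str:
        u = rng.random(self.width)
        cum = np.cumsum(self.pwm, axis=0)
        cols = (u[None, :] > cum).sum(axis=0)
        return "".join(BASES[c] for c in cols)


# Anchor: stands in for the principal TF's core site.  Co-factors: one
# motif per activity pattern (the set of tissues where that co-factor is
# expressed); the pattern {all tissues except t} produces down-binding in t,
# the pattern {t} produces up-binding in t.
DEFAULT_ANCHOR = MotifModel.from_consensus("anchor", "CTGTCAG")

_DEFAULT_COFACTOR_CONSENSI = {
    (1, 2): "ATCAATC",
    (0, 2): "GGATTAC",
    (0, 1): "CCATTGT",
    (0,): "TGACTCA",
    (1,): "GAGGAAC",
    (2,): "CACGTGA",
}


def default_cofactor_motifs(n_tissues: int = 3) -> dict[tuple[int, ...], MotifModel]:
    """One co-factor motif per activity pattern needed to realise every
    up-/down-binding class of an ``n_tissues``-tissue design."""
    if n_tissues != 3:
        raise ValueError("default co-factor motifs are defined for the 3-tissue design")
    return {pattern: MotifModel.from_consensus(f"cofactor_{'-'.join(map(str, pattern))}", cons)
            for pattern, cons in _DEFAULT_COFACTOR_CONSENSI.items()}


@dataclass
class SimulationConfig:
    n_regions_per_class: int = 100
    region_length_range: tuple[int, int] = (200, 2000)
    n_tissues: int = 3
    replicates_per_tissue: tuple[int, ...] = (2, 2, 4)
    anchor_motif: MotifModel = field(default_factory=lambda: DEFAULT_ANCHOR)
    cofactor_motifs: dict[tuple[int, ...], MotifModel] | None = None
    cofactor_effect: float = 4.0
    rpkm_noise_sd: float = 0.3
    label_fold_threshold: float = 1.5
    read_depth: int = 50_000
    read_positional_sd: float = 15.0
    seed: int = 0
    # secondary knobs (kept out of the primary signature above)
    base_rpkm: float = 10.0
    region_baseline_sd: float = 0.4   # log-normal sigma of region occupancy
    background_read_fraction: float = 0.2

    def __post_init__(self):
        if self.cofactor_motifs is None:
            self.cofactor_motifs = default_cofactor_motifs(self.n_tissues)
        lo, hi = self.region_length_range
        if not (200 <= lo <= hi <= 2000):
            raise ValueError("region lengths must lie within [200, 2000]")
        if self.n_regions_per_class <= 0 or self.read_depth <= 0:
            raise ValueError("counts must be positive")
        if len(self.replicates_per_tissue) != self.n_tissues:
            raise ValueError("need one replicate count per tissue")
        if any(r <= 0 for r in self.replicates_per_tissue):
            raise ValueError("counts must be positive")
        # effect 1.0 is the null model (no occupancy signal); < 1 is invalid
        if self.cofactor_effect < 1.0:
            raise ValueError("cofactor_effect must be >= 1")
        widest = max(m.width for m in self.cofactor_motifs.values())
        if lo < self.anchor_motif.width + widest:
            raise ValueError(
                f"minimum region length {lo} too short to hold the anchor motif "
                f"and a co-factor motif without overlap")

    @property
    def class_names(self) -> list[str]:
        names = [f"down_t{t}" for t in range(self.n_tissues)]
        names += [f"up_t{t}" for t in range(self.n_tissues)]
        names.append("non_differential")
        return names

    @property
    def replicate_names(self) -> list[str]:
        return [f"t{t}_rep{k}" for t, n in enumerate(self.replicates_per_tissue)
                for k in range(n)]

    def pattern_for_class(self, cls: str) -> tuple[int, ...] | None:
        """Activity pattern of the co-factor planted in regions destined
        for class ``cls`` (None for non-differential regions)."""
        if cls == "non_differential":
            return None
        kind, tissue = cls.split("_t")
        t = int(tissue)
        if kind == "up":
            return (t,)
        return tuple(sorted(set(range(self.n_tissues)) - {t}))


@dataclass
class SimRegion:
    identifier: str
    sequence: str
    intended_class: str
    anchor_site: tuple[int, int]
    true_sites: list[tuple[int, int, str]]  # (start, end, motif name)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    regions: list[SimRegion]
    rpkm: pd.DataFrame                      # regions x replicates
    labels: pd.Series                       # threshold-rule class per region
    validation_reads: tuple[list[tuple[str, int]], list[tuple[str, int]]]

    @property
    def class_names(self) -> list[str]:
        return self.config.class_names

    def to_arrays(self, input_length: int, pseudocount: float = 1.0,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
        """Encode the dataset for model training.

        Returns ``(X, y_class, y_reg, ids)`` where ``X`` is
        (n, 4, input_length) one-hot, ``y_class`` integer labels in the order
        of :attr:`class_names` and ``y_reg`` the log(RPKM + pseudocount)
        matrix (n, n_replicates).
        """
        classes = {c: i for i, c in enumerate(self.class_names)}
        X = np.stack([one_hot_encode(r.sequence, input_length) for r in self.regions])
        ids = [r.identifier for r in self.regions]
        y_class = np.array([classes[self.labels[r.identifier]] for r in self.regions])
        y_reg = np.log(self.rpkm.loc[ids].to_numpy(dtype=np.float64) + pseudocount)
        return X, y_class, y_reg, ids


def _plant(sequence: list[str], motif: MotifModel, rng: np.random.Generator,
           forbidden: tuple[int, int] | None) -> tuple[int, int]:
    """Place one sampled motif instance uniformly at random, avoiding the
    ``forbidden`` interval if given."""
    L, W = len(sequence), motif.width
    while True:
        start = int(rng.integers(0, L - W + 1))
        if forbidden is None or start + W <= forbidden[0] or start >= forbidden[1]:
            break
    inst = motif.sample(rng)
    sequence[start:start + W] = list(inst)
    return start, start + W


def _threshold_label(rpkm_row: np.ndarray, tissue_of_rep: np.ndarray,
                     n_tissues: int, fold_threshold: float) -> str:
    """Mean fold-change labelling: the tissue with the largest absolute log
    fold change of its mean RPKM against the mean of the other tissues'
    replicates sets the class, if that fold exceeds the threshold."""
    best_t, best_lfc = -1, 0.0
    for t in range(n_tissues):
        own = rpkm_row[tissue_of_rep == t].mean()
        rest = rpkm_row[tissue_of_rep != t].mean()
        lfc = np.log(own / rest)
        if abs(lfc) > abs(best_lfc):
            best_t, best_lfc = t, lfc
    if abs(best_lfc) < np.log(fold_threshold):
        return "non_differential"
    return f"up_t{best_t}" if best_lfc > 0 else f"down_t{best_t}"


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a fully labelled dataset with ground-truth co-factor sites.

    Deterministic given ``config.seed``: background sequences are i.i.d.
    uniform over ACGT, one anchor-motif instance is planted per region, one
    co-factor instance per differential-destined region, RPKM values follow
    the multiplicative occupancy model, labels come from the fold-change
    rule, and two validation read replicates are drawn around planted sites.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.region_length_range
    tissue_of_rep = np.array([t for t, n in enumerate(config.replicates_per_tissue)
                              for _ in range(n)])

    regions: list[SimRegion] = []
    for cls in config.class_names:
        pattern = config.pattern_for_class(cls)
        for i in range(config.n_regions_per_class):
            L = int(rng.integers(lo, hi + 1))
            seq = [BASES[b] for b in rng.integers(0, 4, size=L)]
            anchor = _plant(seq, config.anchor_motif, rng, None)
            sites: list[tuple[int, int, str]] = []
            if pattern is not None:
                motif = config.cofactor_motifs[pattern]
                s, e = _plant(seq, motif, rng, forbidden=anchor)
                sites.append((s, e, motif.name))
            regions.append(SimRegion(f"region_{cls}_{i:05d}", "".join(seq),
                                     cls, anchor, sites))

    # occupancy model: RPKM = region baseline * co-factor effect (in active
    # tissues, if a site is present) * per-replicate log-normal noise
    n_rep = len(tissue_of_rep)
    rpkm = np.empty((len(regions), n_rep))
    for i, region in enumerate(regions):
        base = config.base_rpkm * np.exp(rng.normal(0.0, config.region_baseline_sd))
        pattern = config.pattern_for_class(region.intended_class)
        effect = np.ones(n_rep)
        if pattern is not None and region.true_sites:
            effect[np.isin(tissue_of_rep, pattern)] = config.cofactor_effect
        noise = np.exp(rng.normal(0.0, config.rpkm_noise_sd, size=n_rep))
        rpkm[i] = base * effect * noise
    rpkm_df = pd.DataFrame(rpkm, index=[r.identifier for r in regions],
                           columns=config.replicate_names)

    labels = pd.Series(
        [_threshold_label(rpkm[i], tissue_of_rep, config.n_tissues,
                          config.label_fold_threshold)
         for i in range(len(regions))],
        index=rpkm_df.index, name="label")

    # validation reads: two independent replicates concentrated at planted
    # co-factor sites plus a uniform background component
    site_list = [(r, (s + e) // 2) for r in regions for (s, e, _) in r.true_sites]
    replicates: list[list[tuple[str, int]]] = []
    total_span = sum(r.length for r in regions)
    cum = np.cumsum([r.length for r in regions])
    for _rep in range(2):
        reads: list[tuple[str, int]] = []
        n_bg = int(round(config.background_read_fraction * config.read_depth))
        n_signal = config.read_depth - n_bg
        if site_list:
            which = rng.integers(0, len(site_list), size=n_signal)
            offsets = rng.normal(0.0, config.read_positional_sd, size=n_signal)
            for w, off in zip(which, offsets):
                region, centre = site_list[w]
                pos = int(np.clip(round(centre + off), 0, region.length - 1))
                reads.append((region.identifier, pos))
        flat = rng.integers(0, total_span, size=n_bg)
        for f in flat:
            i = int(np.searchsorted(cum, f, "right"))
            off = int(f - (cum[i - 1] if i > 0 else 0))
            reads.append((regions[i].identifier, off))
        replicates.append(reads)

    return SyntheticDataset(config, regions, rpkm_df, labels,
                            (replicates[0], replicates[1]))


# -- serialization -----------------------------------------------------


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as FASTA + BED + TSV files (one contig per region).

    Emits ``regions.fasta``, ``regions.bed``, ``true_sites.bed``,
    ``rpkm.tsv``, ``labels.tsv`` and ``reads_rep{1,2}.bed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("fasta", "regions.fasta"), ("regions", "regions.bed"),
        ("true_sites", "true_sites.bed"), ("anchors", "anchors.bed"),
        ("rpkm", "rpkm.tsv"), ("labels", "labels.tsv"),
        ("reads_rep1", "reads_rep1.bed"), ("reads_rep2", "reads_rep2.bed")]}

    with open(paths["fasta"], "w") as fa:
        for r in ds.regions:
            fa.write(f">{r.identifier}\n")
            for i in range(0, len(r.sequence), 80):
                fa.write(r.sequence[i:i + 80] + "\n")
    with open(paths["regions"], "w") as bed:
        for r in ds.regions:
            bed.write(f"{r.identifier}\t0\t{r.length}\t{r.identifier}\t0\t+\n")
    with open(paths["true_sites"], "w") as bed:
        for r in ds.regions:
            for (s, e, name) in r.true_sites:
                bed.write(f"{r.identifier}\t{s}\t{e}\t{name}\t0\t+\n")
    with open(paths["anchors"], "w") as bed:
        for r in ds.regions:
            s, e = r.anchor_site
            bed.write(f"{r.identifier}\t{s}\t{e}\t{ds.config.anchor_motif.name}\t0\t+\n")
    ds.rpkm.to_csv(paths["rpkm"], sep="\t", index_label="region")
    lab = pd.DataFrame({"label": ds.labels,
                        "intended_class": [r.intended_class for r in ds.regions]},
                       index=ds.labels.index)
    lab.to_csv(paths["labels"], sep="\t", index_label="region")
    for key, reads in (("reads_rep1", ds.validation_reads[0]),
                       ("reads_rep2", ds.validation_reads[1])):
        with open(paths[key], "w") as bed:
            for rid, pos in reads:
                bed.write(f"{rid}\t{pos}\t{pos + 1}\n")
    return paths


def read_dataset(out_dir: str | Path, config: SimulationConfig) -> SyntheticDataset:
    """Round-trip loader for :func:`write_dataset` output."""
    out = Path(out_dir)
    from pyfaidx import Fasta
    fasta = Fasta(str(out / "regions.fasta"), as_raw=True, sequence_always_upper=True)
    rpkm = pd.read_csv(out / "rpkm.tsv", sep="\t", index_col="region")
    lab = pd.read_csv(out / "labels.tsv", sep="\t", index_col="region")
    sites: dict[str, list[tuple[int, int, str]]] = {}
    with open(out / "true_sites.bed") as fh:
        for line in fh:
            chrom, s, e, name = line.split("\t")[:4]
            sites.setdefault(chrom, []).append((int(s), int(e), name.strip()))
    anchors: dict[str, tuple[int, int]] = {}
    with open(out / "anchors.bed") as fh:
        for line in fh:
            chrom, s, e = line.split("\t")[:3]
            anchors[chrom] = (int(s), int(e))
    regions = [SimRegion(rid, str(fasta[rid][:]), lab.loc[rid, "intended_class"],
                         anchors[rid], sites.get(rid, []))
               for rid in rpkm.index]
    reads = []
    for fname in ("reads_rep1.bed", "reads_rep2.bed"):
        rep: list[tuple[str, int]] = []
        with open(out / fname) as fh:
            for line in fh:
                chrom, s = line.split("\t")[:2]
                rep.append((chrom, int(s)))
        reads.append(rep)
    return SyntheticDataset(config, regions, rpkm,
                            lab["label"].rename("label"), (reads[0], reads[1]))
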