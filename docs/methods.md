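# Methods

## Problem and model

`hdspec` clusters tandem mass spectra (MS/MS) so that repeated
acquisitions of the same peptide collapse into one cluster. The method
avoids comparing peak lists directly: each spectrum is projected into a
D-dimensional binary hypervector (HV), and similarity becomes a
normalized Hamming distance computed word-wise on bit-packed vectors.

The pipeline has five stages:

1. **Preprocessing.** Peaks within ±1.5 Da of the precursor m/z or
   outside the fragment window [101, 1500] Da are removed, then peaks
   below 1% of the surviving base peak. Spectra with fewer than 5
   remaining peaks or spanning less than 250 Da are rejected. At most
   the 50 most intense peaks are kept (intensity ties keep the lower
   m/z) and intensities are scaled to unit Euclidean norm.
2. **Bucket division.** Spectrum *i* with precursor m/z and charge C
   receives the integer bucket `floor(C·(m/z − 1.00794)/1.0005079)`:
   1.00794 Da is the mass of the charge carrier and 1.0005079 Da the
   spacing between adjacent clusters of physically possible peptide
   masses. All later stages run independently per bucket, replacing the
   quadratic all-pairs comparison with a sum of per-bucket quadratics.
3. **HD encoding.** Each retained peak is mapped to an m/z bin
   `i = floor((mz − 101)/0.05)` (f = 27980 bins by default) and an
   intensity level `j = clip(ceil(intensity·Q), 1, Q)`. Two codebooks —
   ID HVs **I** (f × D) and level HVs **L** (Q × D) — are generated as
   random-flip chains: the first row is uniform random and each
   successive row flips exactly `flip_id` (resp. `flip_level`) uniformly
   chosen positions of its predecessor, so nearby bins/levels get
   similar HVs. A peak binds `I_i XOR L_j`; the spectrum HV is the
   pointwise majority of its peaks' bound HVs. Even-vote ties take the
   bit of a seeded tie-break HV, keeping the encoding deterministic and
   unbiased.
4. **Distance computation.** `d(h_a, h_b) = popcount(h_a XOR h_b)/D`,
   evaluated on the packed words (ceil(D/32) word operations per pair),
   yielding a condensed per-bucket distance matrix.
5. **Clustering.** Either hierarchical complete linkage
   (scipy) cut at distance `eps`, with resulting singletons relabeled
   −1, or DBSCAN (scikit-learn, precomputed distances) with
   `min_samples = 2`. Complete linkage guarantees every intra-cluster
   pairwise distance ≤ eps; DBSCAN allows chains where only some
   neighbor is within eps. Per-bucket labels are offset to global
   uniqueness in sorted bucket-key order.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `dim` (D) | 2048 | HV length in bits; capacity of the representation |
| `q_levels` (Q) | 16 | intensity quantization levels |
| `eps` | 0.25 | clustering distance threshold in [0, 1] (useful range ≈ 0.2–0.45) |
| `bin_size` | 0.05 Da | fragment m/z bin width; with the [101, 1500] Da window gives f = 27980 |
| `flip_id` | max(1, round(D/2f)) | bits flipped between consecutive ID HVs |
| `flip_level` | max(1, round(D/2Q)) | bits flipped between consecutive level HVs |
| `precursor_removal_tol` | 1.5 Da | half-width of the precursor removal window (covers the isotope envelope at charge ≥ 2) |
| `charges` | {2, 3} | precursor charges retained |

The flip-count defaults make a full walk of the chain flip about D/2
bits, so the first and last entries approach orthogonality (distance
≈ 0.5) while consecutive entries stay nearly identical.

## Quality metrics

Against an (optionally partial) identifier → peptide table:

* **clustered spectra ratio** — spectra in clusters of size ≥ 2 over
  *all* input spectra, rejected ones included;
* **incorrect clustering ratio** — clustered-and-identified spectra
  whose peptide differs from their cluster's most frequent peptide,
  over clustered-and-identified spectra (majority ties leave the count
  unchanged whichever maximal peptide is chosen);
* **completeness** — `1 − H(C|P)/H(C)` in nats from empirical joint
  counts over clustered-and-identified spectra; 1 by convention when
  H(C) = 0. Unidentified spectra are excluded from the two
  label-dependent metrics but kept in the clustered-ratio denominator.

Note completeness is *not* monotone under cluster splitting for
arbitrary labelings (the normalizer H(C) grows too); the familiar
guarantee — splitting a peptide that was wholly contained in one
cluster strictly lowers the score — holds and is what the test suite
asserts.

## Synthetic data

The generator plants known structure: each template is a random
spectrum (uniform peak m/z over [101, 1500] Da, log-normal intensities,
uniform precursor in [400, 1200] m/z at charge 2 or 3) carrying a
distinct synthetic peptide label; replicates apply Gaussian m/z jitter
(sd 0.01 Da), multiplicative log-normal intensity noise (CV 0.2),
Bernoulli peak dropout (p = 0.1), up to 5 spurious peaks, and precursor
jitter (sd 0.001 Da, far below the 1.0005079/C Da bucket width so
replicates co-bucket). The defaults — 100 templates × 20 replicates —
are the study conditions for the recovery checks. The generator does
not emulate fragmentation chemistry, chimeric spectra, or systematic
precursor drift, so passing recovery tests demonstrates correctness of
the pipeline mechanics, not identification-grade performance on real
data.

## Numerical choices

* Bit convention: bit k lives in word `k // 32`, in-word position
  `k % 32` (little-endian within the word); padding bits above D are
  zero. File-level bit exactness of codebook dumps depends on this.
* One seed drives codebook, tie-break HV and fixtures via
  `numpy.random.SeedSequence.spawn`, so runs are reproducible
  byte-for-byte and independent of worker count or batch size; the
  batch encoder is bit-identical to the scalar encoder by construction
  (integer vote sums).
* Bin collisions keep the higher-intensity peak, so each bin
  contributes one bound HV to the majority.
* Entropies use natural logarithms (any base cancels in the ratio).
* Degenerate inputs: buckets of size 0/1 produce no distance matrix and
  their members are labeled −1; an input where nothing survives
  preprocessing still writes a valid header-only assignment table.

## Known limitations

* With f = 27980 ≫ D, the default per-step flip count clamps to 1 and
  the ID chain's correlation length becomes ≈ D/2 bins (≈ 50 Da at
  D = 2048, bin 0.05 Da): m/z locality *widens* with D. Occasionally two
  unrelated spectra sharing a bucket can then encode within eps at
  large D while being well separated at small D. Raising `flip_id`
  sharpens m/z resolution at the cost of inter-bin smoothing.
* Spectra falling just across a bucket boundary are accepted losses;
  there is no cross-bucket neighbor search. The fixture flag
  `precursor_jitter_sd` can be widened deliberately to exercise this
  loss mode.
* Complete-linkage results are order-invariant only for tie-free
  distance matrices; normalized Hamming distances are multiples of 1/D,
  so exact ties are possible in principle.
* The cluster representative is the medoid (member minimizing summed
  Hamming distance, ties to the lowest ordinal) — deliberately simple
  plumbing, not a consensus-spectrum algorithm.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
data: recovery checks use 100 templates × 20 replicates (2000 spectra)
at D ∈ {128, 2048}, oracle-equivalence checks use ≤ 1000 random pairs
and buckets of ≤ 50, chosen so a full run completes in a few minutes on
one CPU core.
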