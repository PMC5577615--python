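"""mytimine: mining linear cationic antimicrobial-peptide precursors
(myticalin-like) from assembled transcriptomes.

The package covers the full discovery chain — six-frame ORF extraction,
signal-peptide gating, sliding-window cationicity filtering, precursor
architecture annotation, proteolytic maturation with C-terminal
amidation, physicochemical characterization, subfamily classification,
majority-rule consensus building and pseudogene screening — together
with a seeded synthetic-transcriptome generator for benchmarking.
"""

from importlib import resources

from .seqcore import (
    TranscriptRecord,
    ProteinRecord,
    OrfCandidate,
    read_fasta,
    translate,
    reverse_complement,
    extract_orfs,
)
from .physchem import (
    PkaTable,
    EXPASY_PKA,
    CompositionProfile,
    WindowScan,
    composition,
    net_charge,
    isoelectric_point,
    window_scan,
    floor_percent,
)
from .precursor import (
    SignalPrediction,
    CleavageSite,
    PrecursorAnnotation,
    MaturePeptide,
    Rejection,
    AnnotationConfig,
    predict_signal_peptide,
    find_dibasic_sites,
    annotate_precursor,
    apply_maturation,
    mature_from_annotation,
)
from .pipeline import (
    FilterConfig,
    CandidateReport,
    ScreenResult,
    SubfamilyCall,
    ConsensusResult,
    PseudogeneCall,
    screen_transcriptome,
    classify_subfamily,
    majority_consensus,
    screen_pseudogene,
    characterize,
)
from .synthetic import (
    SimulationConfig,
    PlantedTruth,
    SimulatedTranscriptome,
    RecoveryMetrics,
    simulate_transcriptome,
    evaluate_recovery,
)

__version__ = "0.1.0"


def reference_peptides_path():
    """Path to the packaged FASTA of reported mature and virtual
    myticalin peptides from the *M. galloprovincialis* draft genome
    (ids A3, A4, A5, C10, C-PG, D-PG1, D-PG2; ``-NH2`` markers kept)."""
    return resources.files(__name__) / "data" / "myticalin_reference.fasta"


def load_reference_peptides():
    """The packaged reference peptides as :class:`ProteinRecord` objects."""
    return read_fasta(str(reference_peptides_path()), alphabet="protein")
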