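"""Exception hierarchy.

Two broad classes matter to callers: input/schema problems (bad files,
malformed templates) and computation problems (atoms or torsions that cannot
be resolved on a given conformer). The CLI maps them to distinct exit codes.
"""


class IdpcalcError(Exception):
    """Base class for all package errors."""


class InputError(IdpcalcError):
    """Unreadable, empty or otherwise unusable input."""


class SchemaError(InputError):
    """A template or results file does not match the expected schema."""


class ComputationError(IdpcalcError):
    """A back-calculation could not be carried out on a conformer."""


class MissingResidueError(ComputationError):
    def __init__(self, resseq):
        self.resseq = resseq
        super().__init__(f"residue {resseq} not present in conformer")


class MissingAtomError(ComputationError):
    def __init__(self, resseq, name):
        self.resseq = resseq
        self.name = name
        super().__init__(f"atom {name!r} of residue {resseq} not found (fallbacks exhausted)")


class AmbiguousAtomError(ComputationError):
    def __init__(self, key):
        self.key = key
        super().__init__(f"duplicate atom after altloc filtering: {key}")


class UndefinedTorsionError(ComputationError):
    """Degenerate (collinear) geometry, or phi requested at the first residue."""
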