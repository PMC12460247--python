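"""Exception hierarchy shared across the compiler, interpreter and runtime."""


class FmlcError(Exception):
    """Base class for all errors raised by this package."""


# -- schema / model layer ----------------------------------------------------

class SchemaError(FmlcError):
    pass


class SchemaUnsupportedError(SchemaError):
    """An XSD construct outside the supported dialect was encountered."""

    def __init__(self, construct: str, location: str = "?"):
        self.construct = construct
        self.location = location
        super().__init__(f"unsupported XSD construct {construct!r} at {location}")


class TypeResolutionError(SchemaError):
    """An element or type reference could not be resolved."""

    def __init__(self, message: str, candidates: tuple = ()):
        self.candidates = tuple(candidates)
        if candidates:
            message = f"{message} (candidates: {', '.join(sorted(candidates))})"
        super().__init__(message)


class InstanceParseError(FmlcError):
    """Instance document does not fit the model (unknown element, bad shape)."""

    def __init__(self, message: str, path: str = ""):
        self.path = path
        super().__init__(f"{message} at {path}" if path else message)


class NamespaceError(InstanceParseError):
    pass


class SerializationError(FmlcError):
    pass


# -- parsing (FML / FHIRPath / StructureMap) ---------------------------------

class ParseError(FmlcError):
    def __init__(self, message: str, line: int = 0, column: int = 0):
        self.line = line
        self.column = column
        loc = f" at line {line}, column {column}" if line else ""
        super().__init__(f"{message}{loc}")


class UnsupportedTransformError(ParseError):
    def __init__(self, transform: str, line: int = 0, column: int = 0):
        self.transform = transform
        super().__init__(f"unsupported transform {transform!r}", line, column)


class UnsupportedFunctionError(ParseError):
    def __init__(self, function: str, line: int = 0, column: int = 0):
        self.function = function
        super().__init__(f"unsupported FHIRPath function {function!r}", line, column)


class UnsupportedFeatureError(FmlcError):
    """Unsupported StructureMap / resource element."""


class ImportError_(FmlcError):
    """Unresolved import URI."""


class ImportCycleError(FmlcError):
    def __init__(self, chain):
        self.chain = list(chain)
        super().__init__("import cycle: " + " -> ".join(self.chain))


# -- compilation -------------------------------------------------------------

class CompileError(FmlcError):
    pass


class AmbiguityError(CompileError):
    pass


# -- execution ---------------------------------------------------------------

class MapRuntimeError(FmlcError):
    pass


class CardinalityError(MapRuntimeError):
    pass


class TranslateError(MapRuntimeError):
    pass


class FhirPathTypeError(MapRuntimeError):
    pass
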