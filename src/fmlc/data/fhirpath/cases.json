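{
  "_comment": "FHIRPath case suite. Each case: expression, input (FHIR-JSON-style object or null), optional variables, expected output collection. Decimal results are written as JSON strings of their lexical form; __NOW__/__TODAY__ stand for the execution-scoped timestamps. Expectations enumerated by hand when the suite was written.",
  "input": {
    "name": [
      {"use": "official", "given": ["Anna", "Maria"], "family": "Muster"},
      {"use": "nickname", "given": ["Ami"], "family": "M"}
    ],
    "birthDate": "1980-04-02",
    "active": true,
    "score": 7,
    "factor": 2.5,
    "items": [{"value": 3}, {"value": 7}, {"value": 9}]
  },
  "cases": [
    {"expression": "'routine'", "expected": ["routine"]},
    {"expression": "1 + 2", "expected": [3]},
    {"expression": "(1 + 2) * 3", "expected": [9]},
    {"expression": "7 - 2", "expected": [5]},
    {"expression": "2 * 3", "expected": [6]},
    {"expression": "7 / 2", "expected": ["3.5"]},
    {"expression": "7 div 2", "expected": [3]},
    {"expression": "7 mod 2", "expected": [1]},
    {"expression": "-5 + 2", "expected": [-3]},
    {"expression": "1.5 + 2.25", "expected": ["3.75"]},
    {"expression": "'ab' + 'cd'", "expected": ["abcd"]},
    {"expression": "'ab' & 'cd'", "expected": ["abcd"]},
    {"expression": "missing & 'x'", "expected": ["x"]},
    {"expression": "name.count()", "expected": [2]},
    {"expression": "name.given.count()", "expected": [3]},
    {"expression": "name.first().given.count()", "expected": [2]},
    {"expression": "name.last().family", "expected": ["M"]},
    {"expression": "name[0].use", "expected": ["official"]},
    {"expression": "name[1].given", "expected": ["Ami"]},
    {"expression": "name[5]", "expected": []},
    {"expression": "name.where(use = 'official').first().family", "expected": ["Muster"]},
    {"expression": "name.where(use = 'official').given", "expected": ["Anna", "Maria"]},
    {"expression": "items.where(value > 5).count()", "expected": [2]},
    {"expression": "items.where(value > 5).value", "expected": [7, 9]},
    {"expression": "items.select(value)", "expected": [3, 7, 9]},
    {"expression": "items.select(value * 2)", "expected": [6, 14, 18]},
    {"expression": "items.value.first()", "expected": [3]},
    {"expression": "items.value.last()", "expected": [9]},
    {"expression": "items.exists()", "expected": [true]},
    {"expression": "missing.exists()", "expected": [false]},
    {"expression": "missing.empty()", "expected": [true]},
    {"expression": "name.empty()", "expected": [false]},
    {"expression": "name.exists(use = 'nickname')", "expected": [true]},
    {"expression": "active", "expected": [true]},
    {"expression": "active.not()", "expected": [false]},
    {"expression": "missing.exists().not()", "expected": [true]},
    {"expression": "score = 7", "expected": [true]},
    {"expression": "score != 7", "expected": [false]},
    {"expression": "score < 10", "expected": [true]},
    {"expression": "score <= 7", "expected": [true]},
    {"expression": "score > 7", "expected": [false]},
    {"expression": "score >= 8", "expected": [false]},
    {"expression": "missing = 1", "expected": []},
    {"expression": "score + factor", "expected": ["9.5"]},
    {"expression": "true and false", "expected": [false]},
    {"expression": "true or false", "expected": [true]},
    {"expression": "true xor true", "expected": [false]},
    {"expression": "false implies true", "expected": [true]},
    {"expression": "missing.exists() and true", "expected": [false]},
    {"expression": "missing and true", "expected": []},
    {"expression": "missing or true", "expected": [true]},
    {"expression": "'abc'.contains('b')", "expected": [true]},
    {"expression": "'abc'.contains('z')", "expected": [false]},
    {"expression": "'abc'.startsWith('ab')", "expected": [true]},
    {"expression": "'abcdef'.substring(2)", "expected": ["cdef"]},
    {"expression": "'abcdef'.substring(1, 3)", "expected": ["bcd"]},
    {"expression": "'abcdef'.substring(9)", "expected": []},
    {"expression": "score.toString()", "expected": ["7"]},
    {"expression": "'42'.toInteger()", "expected": [42]},
    {"expression": "'x'.toInteger()", "expected": []},
    {"expression": "iif(score > 5, 'high', 'low')", "expected": ["high"]},
    {"expression": "iif(missing.exists(), 'y', 'n')", "expected": ["n"]},
    {"expression": "now()", "expected": ["__NOW__"]},
    {"expression": "today()", "expected": ["__TODAY__"]},
    {"expression": "score is Integer", "expected": [true]},
    {"expression": "score is String", "expected": [false]},
    {"expression": "(score as Integer) + 1", "expected": [8]},
    {"expression": "name.where(given.contains('Ami')).use", "expected": ["nickname"]},
    {"expression": "items.where(value > %threshold).count()",
     "variables": {"threshold": 5}, "expected": [2]},
    {"expression": "$this.score", "expected": [7]},
    {"expression": "1 | 2 | 1", "expected": [1, 2]},
    {"expression": "name.given | name.family",
     "expected": ["Anna", "Maria", "Ami", "Muster", "M"]},
    {"expression": "@2020-01-01 < @2021-06-30", "expected": [true]},
    {"expression": "birthDate.substring(0, 4).toInteger()", "expected": [1980]}
  ]
}
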