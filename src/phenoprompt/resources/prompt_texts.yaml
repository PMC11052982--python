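# Versioned prompt building-block texts.
#
# Blocks: task_instruction, task guidance (entity definitions plus optional
# distinguishing characteristics), output specification, example header, and
# output-retrieval cue. Placeholders are filled by the prompt builder.
version: 1

entity_display_names:
  rare_disease: "rare disease"
  disease: "disease"
  symptom: "symptom"
  sign: "sign"

task_instruction: >-
  Identify all rare diseases, diseases, symptoms, and signs mentioned in the
  input text and extract their exact names from the input text. Copy each
  name verbatim as it appears; do not rephrase, shorten, or expand any name.

entity_definitions:
  rare_disease: >-
    Diseases which affect a small number of people compared to the general
    population
  disease: >-
    An abnormal condition of a part, organ, or system of an organism resulting
    from various causes, such as infection, inflammation, environmental
    factors, or genetic defect, and characterized by an identifiable group of
    signs, symptoms, or both
  symptom: >-
    A physical or mental problem that may indicate a disease or condition;
    cannot be seen and do not show up on medical tests
  sign: >-
    A physical or mental problem that may indicate a disease or condition;
    can be seen and shows up on medical tests

characteristics:
  rare_disease: >-
    Rare diseases often come with terms like "rare", "uncommon", or mentions
    of specific low-prevalence numbers. For example, in the sentence,
    "Ablepharon-Macrostomia Syndrome (AMS) is an extremely rare inherited
    disorder," "Ablepharon-Macrostomia Syndrome" and "AMS" are rare diseases,
    but "inherited disorder" is not.
  disease: >-
    Diseases are generally recognized medical conditions. The mention of a
    disease might not necessarily come with descriptors of its prevalence
    unless it's rare. For example, in the sentence, "Ablepharon-Macrostomia
    Syndrome (AMS) is an extremely rare inherited disorder," "inherited
    disorder" is a disease.
  symptom: >-
    Symptoms are subjective and detected by the patient. For example, in the
    sentence, "In the acute form, drowsiness, coma, and seizures may occur,"
    "drowsiness" is a symptom, but "coma" and "seizures" are not.
  sign: >-
    Signs can be measured or observed and don't rely on the patient's
    subjective reporting. For example, in the sentence, "In the acute form,
    drowsiness, coma, and seizures may occur," "coma" and "seizures" are
    signs, but "drowsiness" is not.

output_specification: >-
  Report the extracted entities as one line per entity type, in the format
  "<entity type>: <name>, <name>, ...", using exactly the four entity type
  labels "rare disease", "disease", "symptom", and "sign". If no entities of
  a type are present, write "none" for that type.

example_header: >-
  Here is an example of an input text and its correct output.

output_retrieval: >-
  Now provide the output for the input text above.
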