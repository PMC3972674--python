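(* Rule-language grammar: the BNGL subset accepted by spatialrules.model.
   Comments start with '#'; blank lines are ignored; one statement per line. *)

model         = { block } ;
block         = "begin parameters"     { parameter }  "end parameters"
              | "begin molecule types" { molecule }   "end molecule types"
              | "begin reaction rules" { rule }       "end reaction rules" ;

parameter     = ident number ;

molecule      = ident "(" [ site-decl { "," site-decl } ] ")" ;
site-decl     = ident { "~" ident } ;
                (* duplicate site names allowed (generic, interchangeable
                   sites); "~" labels list the allowed modification states,
                   the first being the initial state *)

rule          = [ ident ":" ] side "->" side [ rate ] [ "@" ident ] ;
side          = complex { "+" complex } ;
complex       = molecule-pat { "." molecule-pat } ;
molecule-pat  = ident "(" [ site-pat { "," site-pat } ] ")" ;
site-pat      = ident [ "~" ident ] [ bond ] ;
bond          = "!" integer      (* named bond; each label exactly twice *)
              | "!+"             (* bound to anything *)
              | "!?" ;           (* bond state unspecified *)
                (* a mentioned site without a bond marker must be UNBOUND;
                   omitted sites are wildcards *)
rate          = number | ident ; (* literal, or a parameter name *)

ident         = letter-or-underscore { letter-or-digit-or-underscore } ;

(* Semantic constraints enforced after parsing:
   - both rule sides mention the same molecules (conservation) and the same
     site occurrences; only bonds and modification states may differ;
   - at most one bond is formed or broken per rule;
   - "+"-separated complexes map to distinct molecules but may belong to the
     same assembled complex (ring closure is geometry's decision);
   - rules are unidirectional: write a reverse rule for a reversible
     reaction. *)
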